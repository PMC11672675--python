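"""Synthetic numbered-repertoire generation with planted structure.

The generator emulates the statistical shape of a large numbered
antibody variable-domain repertoire at the level the conservation
statistic sees: independent per-position amino-acid distributions with
configurable occupancy, CDR loop-length variation realized through each
scheme's documented insertion sites, a kappa/lambda light-chain mixture
with species-specific ratios, and planted conservation structure —
one-residue-dominated framework columns, near-flat Tyr-enriched CDR
columns, conserved Cys/Trp anchors, hydrophobic CDR1 pivot columns, and
the RFSGSXSG light-chain strand.

Because every planted distribution is known exactly, the module also
exposes analytic oracles (:func:`analytic_re`,
:func:`analytic_distributions`) for parameter-recovery tests: the
empirical per-position RE of a sampled repertoire converges to the
analytic RE of the planted distributions as the sample grows.

Positions are independent across sites and sequences; correlated-site
realism (germline linkage, somatic hypermutation) is deliberately out of
scope since the statistic under study is position-wise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from igentropy.schemes import (
    AMINO_ACIDS,
    SchemeError,
    SchemePosition,
    equivalence_table,
    general_cdr,
    parse_position_label,
)
from igentropy.frequencies import ReferenceDistribution
from igentropy.entropy import relative_entropy, NATS
from igentropy.repio import Repertoire, records_from_arrays

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

SPECIES = ("human", "mouse")

#: kappa fraction of light chains: roughly 2:1 kappa:lambda in humans,
#: ~5% lambda in mice.
KAPPA_FRACTION = {"human": 2 / 3, "mouse": 0.95}


def _simplex(spec: dict[str, float], rest: Optional[float] = None
             ) -> np.ndarray:
    """Distribution with named masses, remainder spread uniformly."""
    vec = np.zeros(20)
    for aa, w in spec.items():
        vec[_AA_INDEX[aa]] = w
    remainder = 1.0 - vec.sum()
    free = vec == 0
    if free.any() and remainder > 0:
        vec[free] = remainder / free.sum()
    return vec / vec.sum()


def _dominant(aa: str, mass: float) -> np.ndarray:
    return _simplex({aa: mass})


@dataclass(frozen=True)
class PositionSpec:
    """Generative description of one scheme position.

    ``occupancy`` is the marginal probability a sequence carries a
    residue there (for loop-extra positions the loop-length distribution
    overrides it); ``distribution`` is the planted 20-simplex.
    """

    position: SchemePosition
    occupancy: float
    distribution: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise SchemeError("occupancy must lie in [0, 1]")
        d = np.asarray(self.distribution, dtype=float)
        if d.shape != (20,) or (d < 0).any() or abs(d.sum() - 1) > 1e-9:
            raise SchemeError("distribution must be a 20-simplex")
        object.__setattr__(self, "distribution", d)

    @classmethod
    def from_dirichlet(cls, position: SchemePosition, occupancy: float,
                      concentration: Sequence[float],
                      rng: np.random.Generator) -> "PositionSpec":
        """Realize the distribution from a Dirichlet draw at build time."""
        conc = np.asarray(concentration, dtype=float)
        if conc.shape != (20,) or (conc <= 0).any():
            raise SchemeError("concentration must be a positive 20-vector")
        return cls(position, occupancy, rng.dirichlet(conc))


@dataclass(frozen=True)
class LoopSpec:
    """Length variation of one CDR loop via ordered insertion positions.

    A sequence occupies the first ``k`` of ``extras``, with ``k`` drawn
    from ``length_probs`` (index = number of extra residues).
    """

    name: str
    extras: tuple[PositionSpec, ...]
    length_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        probs = np.asarray(self.length_probs, dtype=float)
        if abs(probs.sum() - 1) > 1e-9 or (probs < 0).any():
            raise SchemeError("length_probs must be a probability vector")
        if len(self.length_probs) != len(self.extras) + 1:
            raise SchemeError("length_probs must cover 0..len(extras)")

    def extra_occupancy(self, j: int) -> float:
        """Marginal probability that extra position j is occupied."""
        return float(sum(self.length_probs[j + 1:]))


@dataclass(frozen=True)
class ClassTemplate:
    """Per-light-class (or heavy) template: canonical positions + loops."""

    positions: tuple[PositionSpec, ...]
    loops: tuple[LoopSpec, ...] = ()


@dataclass(frozen=True)
class RepertoireSpec:
    """Generative description of a synthetic numbered repertoire."""

    chain: str
    scheme: str
    species: str
    kappa_fraction: float
    templates: dict[str, ClassTemplate]
    seed: int = 0
    planted_deltas: tuple[str, ...] = ()

    def classes(self) -> tuple[str, ...]:
        return ("kappa", "lambda") if self.chain == "L" else ("heavy",)

    def class_probability(self, cls: str) -> float:
        if self.chain == "H":
            return 1.0
        return self.kappa_fraction if cls == "kappa" else 1 - self.kappa_fraction

    def all_position_specs(self, cls: str) -> list[tuple[PositionSpec, float]]:
        """(spec, marginal occupancy) for every position of one class."""
        tpl = self.templates[cls]
        out = [(ps, ps.occupancy) for ps in tpl.positions]
        for loop in tpl.loops:
            for j, ps in enumerate(loop.extras):
                out.append((ps, loop.extra_occupancy(j)))
        out.sort(key=lambda t: t[0].position.sort_key())
        return out

    def to_config(self) -> str:
        """Serialize as a JSON text config (reversible)."""
        def ps(p: PositionSpec, probs=None) -> dict:
            return {"position": p.position.label,
                    "occupancy": p.occupancy,
                    "distribution": [round(float(x), 12)
                                     for x in p.distribution]}

        doc = {
            "chain": self.chain, "scheme": self.scheme,
            "species": self.species, "kappa_fraction": self.kappa_fraction,
            "seed": self.seed, "planted_deltas": list(self.planted_deltas),
            "templates": {
                cls: {
                    "positions": [ps(p) for p in tpl.positions],
                    "loops": [{"name": lp.name,
                               "length_probs": list(lp.length_probs),
                               "extras": [ps(p) for p in lp.extras]}
                              for lp in tpl.loops],
                } for cls, tpl in self.templates.items()
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_config(cls, text: str) -> "RepertoireSpec":
        doc = json.loads(text)
        scheme = doc["scheme"]

        def ps(d: dict) -> PositionSpec:
            return PositionSpec(
                parse_position_label(d["position"], scheme),
                d["occupancy"], np.asarray(d["distribution"]))

        templates = {
            name: ClassTemplate(
                positions=tuple(ps(p) for p in tpl["positions"]),
                loops=tuple(LoopSpec(lp["name"],
                                     tuple(ps(p) for p in lp["extras"]),
                                     tuple(lp["length_probs"]))
                            for lp in tpl["loops"]))
            for name, tpl in doc["templates"].items()}
        return cls(chain=doc["chain"], scheme=scheme,
                   species=doc["species"],
                   kappa_fraction=doc["kappa_fraction"],
                   templates=templates, seed=doc["seed"],
                   planted_deltas=tuple(doc["planted_deltas"]))


# --------------------------------------------------------------------------
# default planted structure
# --------------------------------------------------------------------------

# conserved anchors (Kabat labels): the Cys pair bracketing each domain,
# the four >90%-conserved framework Trp, and the RFSGSXSG light strand
# (Kabat L61-L68; its sixth column, L66, is only ~58% Gly).
_ANCHORS = {
    "L": {"L23": _dominant("C", 0.95), "L35": _dominant("W", 0.95),
          "L88": _dominant("C", 0.95),
          "L61": _dominant("R", 0.92), "L62": _dominant("F", 0.92),
          "L63": _dominant("S", 0.92), "L64": _dominant("G", 0.92),
          "L65": _dominant("S", 0.92), "L66": _dominant("G", 0.58),
          "L67": _dominant("S", 0.92), "L68": _dominant("G", 0.92)},
    "H": {"H22": _dominant("C", 0.95), "H36": _dominant("W", 0.95),
          "H47": _dominant("W", 0.95), "H92": _dominant("C", 0.95),
          "H103": _dominant("W", 0.95)},
}

# near-flat, Ser/Gly/Tyr-enriched CDR column
_CDR_DIST = _simplex({"S": 0.149, "G": 0.111, "Y": 0.110,
                      "T": 0.06, "A": 0.05, "D": 0.05})

# CDR1 pivot columns (Kabat labels); hydrophobic-dominant, with the
# kappa/lambda contrast at L27B/L28 that drives the cross-species
# divergence when the kappa:lambda ratio differs.
_PIVOTS = {
    ("L", "kappa"): {
        "L27B": _simplex({"I": 0.25, "V": 0.20, "L": 0.15,
                          "S": 0.08, "N": 0.05})},
    ("L", "lambda"): {
        "L27B": _simplex({"N": 0.45, "D": 0.19, "S": 0.08}),
        "L28": _simplex({"V": 0.30, "I": 0.25, "L": 0.14})},
    ("H", "heavy"): {
        "H29": _simplex({"F": 0.71, "Y": 0.06, "S": 0.05})},
}

# insertion-coded loop-extra column: Gly/Ser-rich
_INSERTION_DIST = _simplex({"G": 0.30, "S": 0.20, "Y": 0.10})

# loop extras per scheme: ordered insertion labels and length distribution
_LOOP_EXTRAS = {
    ("L", "kabat"): [("CDR1", ["L27C", "L27D"], (0.80, 0.15, 0.05)),
                     ("CDR3", ["L95A", "L95B", "L95C"],
                      (0.70, 0.15, 0.10, 0.05))],
    ("L", "chothia"): [("CDR1", ["L30C", "L30D"], (0.80, 0.15, 0.05)),
                       ("CDR3", ["L95A", "L95B", "L95C"],
                        (0.70, 0.15, 0.10, 0.05))],
    ("L", "imgt"): [("CDR1", ["L37", "L38"], (0.80, 0.15, 0.05)),
                    ("CDR3", ["L111.1", "L112.1", "L111.2"],
                     (0.70, 0.15, 0.10, 0.05))],
    ("L", "aho"): [("CDR1", ["L37", "L38"], (0.80, 0.15, 0.05)),
                   ("CDR3", ["L116", "L117", "L118"],
                    (0.70, 0.15, 0.10, 0.05))],
    ("H", "kabat"): [("CDR3", ["H100A", "H100B", "H100C"],
                      (0.55, 0.20, 0.15, 0.10))],
    ("H", "imgt"): [("CDR3", ["H111.1", "H112.1", "H111.2"],
                     (0.55, 0.20, 0.15, 0.10))],
    ("H", "aho"): [("CDR3", ["H117", "H118", "H119"],
                    (0.55, 0.20, 0.15, 0.10))],
}
for _alias in ("chothia", "consensus_chothia", "abm"):
    _LOOP_EXTRAS[("H", _alias)] = _LOOP_EXTRAS[("H", "kabat")]
for _alias in ("consensus_chothia", "abm"):
    _LOOP_EXTRAS[("L", _alias)] = _LOOP_EXTRAS[("L", "chothia")]

_FR_DOMINANT_MASS = 0.90


def _canonical_columns(chain: str, scheme: str) -> list[tuple[str, str]]:
    """(scheme label, kabat label) per canonical column, in order."""
    rows = [r for r in equivalence_table() if r["chain"] == chain]
    return [(r[scheme], r["kabat"]) for r in rows]


def default_spec(chain: str, scheme: str, species: str = "human"
                 ) -> RepertoireSpec:
    """The default planted repertoire description for a chain/scheme.

    Framework columns are dominated by one residue (mass 0.90, cycling
    deterministically through the alphabet), conserved anchors carry
    0.92-0.95 dominant mass, general-CDR columns are near-flat and
    Ser/Gly/Tyr-enriched, and the CDR1 pivot columns are hydrophobic-
    dominant with the kappa/lambda contrast described in the module
    docstring.  Species sets the kappa fraction (human 2/3, mouse 0.95);
    the per-class templates are otherwise species-independent, so
    cross-species divergence arises from the light-class mixture (or
    from :func:`planted_pair` deltas).
    """
    if chain not in ("L", "H"):
        raise SchemeError(f"unknown chain {chain!r}")
    if species not in SPECIES:
        raise SchemeError(f"unsupported species {species!r}")
    if (chain, scheme) not in _LOOP_EXTRAS:
        raise SchemeError(f"unsupported chain/scheme ({chain}, {scheme})")

    columns = _canonical_columns(chain, scheme)
    classes = ("kappa", "lambda") if chain == "L" else ("heavy",)
    templates: dict[str, ClassTemplate] = {}
    for cls in classes:
        pivots = _PIVOTS[(chain, cls)]
        specs = []
        for i, (label, kabat_label) in enumerate(columns):
            kpos = parse_position_label(kabat_label, "kabat")
            if kabat_label in pivots:
                dist = pivots[kabat_label]
            elif kabat_label in _ANCHORS[chain]:
                dist = _ANCHORS[chain][kabat_label]
            elif general_cdr(kpos):
                dist = _CDR_DIST
            else:
                dist = _dominant(AMINO_ACIDS[(7 * i) % 20],
                                 _FR_DOMINANT_MASS)
            specs.append(PositionSpec(parse_position_label(label, scheme),
                                      1.0, dist))
        loops = tuple(
            LoopSpec(name,
                     tuple(PositionSpec(parse_position_label(lab, scheme),
                                        1.0, _INSERTION_DIST)
                           for lab in labels),
                     probs)
            for name, labels, probs in _LOOP_EXTRAS[(chain, scheme)])
        templates[cls] = ClassTemplate(positions=tuple(specs), loops=loops)

    kappa_fraction = KAPPA_FRACTION[species] if chain == "L" else 1.0
    return RepertoireSpec(chain=chain, scheme=scheme, species=species,
                          kappa_fraction=kappa_fraction, templates=templates)


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def sample_repertoire(spec: RepertoireSpec, n: int, seed: int) -> Repertoire:
    """Draw ``n`` independent numbered sequences from the spec.

    Deterministic for fixed (spec, n, seed): the light-class assignment,
    per-loop lengths, per-position occupancy and residues are drawn from
    a single seeded generator in a fixed order.
    """
    if n < 1:
        raise SchemeError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"{spec.species}_{spec.chain}_{i:06d}" for i in range(n)]

    if spec.chain == "L":
        is_kappa = rng.random(n) < spec.kappa_fraction
        class_of = np.where(is_kappa, "kappa", "lambda")
    else:
        class_of = np.full(n, "heavy")

    records = []
    for cls in spec.classes():
        idx = np.nonzero(class_of == cls)[0]
        n_c = len(idx)
        if n_c == 0:
            continue
        specs_occ = spec.all_position_specs(cls)
        positions = [ps.position for ps, _ in specs_occ]
        tpl = spec.templates[cls]
        loop_extra_rank = {ps.position.label: (loop, j)
                           for loop in tpl.loops
                           for j, ps in enumerate(loop.extras)}
        loop_k = {loop.name: rng.choice(len(loop.length_probs), size=n_c,
                                        p=loop.length_probs)
                  for loop in tpl.loops}
        occ = np.empty((n_c, len(positions)), dtype=bool)
        res = np.empty((n_c, len(positions)), dtype=np.int8)
        for j, (ps, _marginal) in enumerate(specs_occ):
            rank = loop_extra_rank.get(ps.position.label)
            if rank is not None:
                loop, r = rank
                occ[:, j] = loop_k[loop.name] > r
            elif ps.occupancy >= 1.0:
                occ[:, j] = True
            else:
                occ[:, j] = rng.random(n_c) < ps.occupancy
            res[:, j] = rng.choice(20, size=n_c, p=ps.distribution)
        records.extend(records_from_arrays(
            ids=[ids[i] for i in idx], species=spec.species,
            chain=spec.chain,
            light_classes=[cls if spec.chain == "L" else "not_applicable"]
            * n_c,
            scheme=spec.scheme, positions=positions,
            residue_matrix=res, occupancy_mask=occ))
    records.sort(key=lambda r: r.id)
    return Repertoire(records=tuple(records), chain=spec.chain,
                      scheme=spec.scheme,
                      provenance=f"synthetic:{spec.species}:{seed}")


def planted_pair(base: RepertoireSpec,
                 deltas: Sequence[tuple[Union[str, SchemePosition],
                                        np.ndarray]],
                 ) -> tuple[RepertoireSpec, RepertoireSpec]:
    """A spec pair differing only at the delta positions.

    The second spec replaces the planted distribution at each named
    position (in every class template); the divergent label set is
    recorded in its ``planted_deltas`` for recovery tests.  Emulates
    cross-species positional divergence.
    """
    delta_map: dict[str, np.ndarray] = {}
    for pos, dist in deltas:
        label = pos.label if isinstance(pos, SchemePosition) else str(pos)
        delta_map[label] = np.asarray(dist, dtype=float)

    known = {ps.position.label
             for tpl in base.templates.values()
             for ps in tpl.positions}
    unknown = set(delta_map) - known
    if unknown:
        raise SchemeError(f"delta at unknown position(s): {sorted(unknown)}")

    new_templates = {}
    for cls, tpl in base.templates.items():
        new_positions = tuple(
            replace(ps, distribution=delta_map[ps.position.label])
            if ps.position.label in delta_map else ps
            for ps in tpl.positions)
        new_templates[cls] = ClassTemplate(positions=new_positions,
                                           loops=tpl.loops)
    other = replace(base, templates=new_templates,
                    planted_deltas=tuple(sorted(delta_map)))
    return base, other


# --------------------------------------------------------------------------
# analytic oracles
# --------------------------------------------------------------------------

def analytic_distributions(spec: RepertoireSpec) -> pd.DataFrame:
    """Expected occupancy and conditional residue distribution per position.

    Marginalizes over the light-class mixture: the expected distribution
    at a position, conditional on it being occupied, is the class-
    probability- and occupancy-weighted mixture of the class templates.
    Returns a frame indexed by label with ``occupancy`` and one column
    per amino acid.
    """
    acc: dict[str, np.ndarray] = {}
    occ_acc: dict[str, float] = {}
    order: dict[str, tuple] = {}
    for cls in spec.classes():
        w_cls = spec.class_probability(cls)
        for ps, occ in spec.all_position_specs(cls):
            label = ps.position.label
            w = w_cls * occ
            acc[label] = acc.get(label, np.zeros(20)) + w * ps.distribution
            occ_acc[label] = occ_acc.get(label, 0.0) + w
            order[label] = ps.position.sort_key()
    labels = sorted(acc, key=order.get)
    rows = []
    for label in labels:
        w = occ_acc[label]
        dist = acc[label] / w if w > 0 else np.full(20, np.nan)
        rows.append([label, w] + list(dist))
    return pd.DataFrame(rows, columns=["position", "occupancy"]
                        + list(AMINO_ACIDS)).set_index("position")


def analytic_re(spec: RepertoireSpec, ref: ReferenceDistribution,
                base: float = NATS) -> pd.Series:
    """Exact RE of each planted (mixture) distribution against ``ref``.

    The oracle for empirical-RE convergence tests: at a fully occupied
    position the empirical RE of a sampled repertoire converges to this
    value as n grows.
    """
    dists = analytic_distributions(spec)
    values = {}
    for label, row in dists.iterrows():
        p = row[list(AMINO_ACIDS)].to_numpy(dtype=float)
        if np.isnan(p).any():
            continue
        values[label] = relative_entropy(p, ref, base)
    return pd.Series(values, dtype=float)
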