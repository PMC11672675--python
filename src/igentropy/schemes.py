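"""Numbering-scheme position algebra and region catalogs.

Antibody numbering schemes assign standardized labels to variable-domain
residues so that structurally equivalent positions share a label across
antibodies.  Length variation in the hypervariable loops is absorbed by
*insertion codes*: lettered sub-positions in the Kabat family of schemes
(``L27A``), fractional sub-positions in IMGT (``H111.1``).  This module
provides:

* :class:`SchemePosition` — a chain-qualified, insertion-aware residue
  coordinate under a named scheme, with lossless text round-tripping;
* a strict total order on positions (:func:`compare_positions`),
  including the IMGT CDR3 convention where the 111.x sub-positions
  ascend and the 112.x sub-positions descend back toward 112;
* :class:`RegionCatalog` — the CDR/framework partition of each scheme
  (Kabat, Chothia, consensus Chothia, AbM, IMGT) plus the "general CDR"
  union of all scheme CDR definitions, expressed on Kabat numbering;
* a packaged, versioned inter-scheme equivalence table for framework
  positions and canonical-length CDRs (:func:`convert_scheme`).

The equivalence table is a curated per-chain column model, not a
renumbering engine: converting a position outside the table raises
:class:`SchemeError` rather than guessing.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical amino acids, alphabetical by one-letter code."""

CHAINS = ("L", "H")

SCHEMES = ("kabat", "chothia", "consensus_chothia", "abm", "imgt", "aho")
KABAT_FAMILY = frozenset({"kabat", "chothia", "consensus_chothia", "abm"})

#: catalogued schemes also include the "general" union pseudo-scheme,
#: which lives on Kabat numbering.
CATALOG_SCHEMES = ("kabat", "chothia", "consensus_chothia", "abm", "imgt",
                   "general")

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
CDR_REGIONS = ("CDR1", "CDR2", "CDR3")

EQUIVALENCE_TABLE_VERSION = "v1"
ANNOTATION_TABLE_VERSION = "v1"


class SchemeError(ValueError):
    """Invalid position label, scheme/chain mismatch, or conversion failure."""


# --------------------------------------------------------------------------
# scheme spans and insertion-site inventories
# --------------------------------------------------------------------------

# maximum base number per (scheme, chain)
_SPANS = {
    ("kabat", "L"): 109, ("kabat", "H"): 113,
    ("chothia", "L"): 109, ("chothia", "H"): 113,
    ("consensus_chothia", "L"): 109, ("consensus_chothia", "H"): 113,
    ("abm", "L"): 109, ("abm", "H"): 113,
    ("imgt", "L"): 128, ("imgt", "H"): 128,
    ("aho", "L"): 149, ("aho", "H"): 149,
}


def _letters(last: str) -> tuple[str, ...]:
    return tuple(chr(c) for c in range(ord("A"), ord(last) + 1))


def _fracs(last: int) -> tuple[str, ...]:
    return tuple(f".{i}" for i in range(1, last + 1))


# allowed insertion tags per (scheme, chain, base number); lettered sites
# follow each scheme's documented insertion-site inventory, fractional
# sites are the IMGT sub-positions.
_KABAT_SITES = {
    ("L", 27): _letters("F"), ("L", 39): _letters("A"),
    ("L", 54): _letters("E"), ("L", 66): _letters("H"),
    ("L", 95): _letters("F"), ("L", 106): _letters("A"),
    ("H", 6): _letters("D"), ("H", 35): _letters("H"),
    ("H", 52): _letters("G"), ("H", 82): _letters("E"),
    ("H", 100): _letters("T"),
}
_CHOTHIA_SITES = {
    ("L", 30): _letters("F"), ("L", 39): _letters("A"),
    ("L", 54): _letters("E"), ("L", 66): _letters("H"),
    ("L", 95): _letters("F"), ("L", 106): _letters("A"),
    ("H", 6): _letters("D"), ("H", 31): _letters("H"),
    ("H", 52): _letters("G"), ("H", 82): _letters("E"),
    ("H", 100): _letters("T"),
}
_ABM_SITES = {
    ("L", 30): _letters("F"), ("L", 40): _letters("A"),
    ("L", 52): _letters("E"), ("L", 68): _letters("H"),
    ("L", 95): _letters("F"), ("L", 106): _letters("A"),
    ("H", 7): _letters("D"), ("H", 31): _letters("H"),
    ("H", 52): _letters("G"), ("H", 72): _letters("E"),
    ("H", 100): _letters("T"),
}
_IMGT_SITES = {
    ("L", 46): _fracs(1), ("L", 84): _fracs(6),
    ("L", 111): _fracs(6), ("L", 112): _fracs(6),
    ("H", 10): _fracs(3), ("H", 32): _fracs(4),
    ("H", 60): _fracs(4), ("H", 84): _fracs(2),
    ("H", 111): _fracs(6), ("H", 112): _fracs(6),
}

INSERTION_SITES: dict[str, dict[tuple[str, int], tuple[str, ...]]] = {
    "kabat": _KABAT_SITES,
    "chothia": _CHOTHIA_SITES,
    "consensus_chothia": _CHOTHIA_SITES,
    "abm": _ABM_SITES,
    "imgt": _IMGT_SITES,
    "aho": {},  # Aho absorbs length variation with whole-number gaps
}


# --------------------------------------------------------------------------
# SchemePosition
# --------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^([LH])(\d+)([A-T]|\.\d)?$")


@dataclass(frozen=True, order=False)
class SchemePosition:
    """A residue coordinate under a named numbering scheme.

    ``insertion`` is ``None`` for an untagged position, a single letter
    ``"A"``–``"T"`` for Kabat-family insertion codes, or a fractional
    suffix ``".1"``–``".6"`` for IMGT-style sub-positions.
    """

    chain: str
    number: int
    insertion: Optional[str]
    scheme: str

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise SchemeError(f"unknown chain {self.chain!r}")
        if self.scheme not in SCHEMES:
            raise SchemeError(f"unknown scheme {self.scheme!r}")
        span = _SPANS[(self.scheme, self.chain)]
        if not 1 <= self.number <= span:
            raise SchemeError(
                f"base number {self.number} outside {self.scheme} {self.chain}"
                f"-chain span 1..{span}")
        if self.insertion is not None:
            allowed = INSERTION_SITES[self.scheme].get(
                (self.chain, self.number), ())
            if self.insertion not in allowed:
                raise SchemeError(
                    f"insertion tag {self.insertion!r} not permitted at "
                    f"{self.chain}{self.number} under the {self.scheme} scheme")

    @property
    def label(self) -> str:
        """Canonical text form, e.g. ``"L27B"`` or ``"H111.1"``."""
        return f"{self.chain}{self.number}{self.insertion or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    def sort_key(self) -> tuple[int, float]:
        """Ordering key within one (chain, scheme).

        Base number first; at equal base number the untagged position
        precedes tagged ones, lettered tags ascend alphabetically, and
        fractional tags ascend — except at IMGT/Aho-style position 112,
        where the published CDR3 convention runs
        ``111 < 111.1 < … < 112.2 < 112.1 < 112``: there the fractional
        tags descend and *precede* the untagged 112.
        """
        n, ins = self.number, self.insertion
        if ins is None:
            return (n, 0.0)
        if ins.startswith("."):
            rank = float(ins[1:])
            if n == 112:
                return (n, -rank)  # 112.6 < ... < 112.1 < 112
            return (n, rank)
        return (n, float(ord(ins) - ord("A") + 1))

    def with_scheme(self, scheme: str) -> "SchemePosition":
        """Relabel in place (no renumbering); used internally."""
        return SchemePosition(self.chain, self.number, self.insertion, scheme)


def parse_position_label(text: str, scheme: str) -> SchemePosition:
    """Parse a position label such as ``"L27B"`` or ``"H111.1"``.

    Raises :class:`SchemeError` on malformed text, an insertion tag not
    enumerated for that site under the scheme, or a base number outside
    the scheme span.  Formatting the result back (``.label``) yields the
    canonical input text.
    """
    m = _LABEL_RE.match(text.strip())
    if m is None:
        raise SchemeError(f"malformed position label {text!r}")
    chain, num, ins = m.group(1), int(m.group(2)), m.group(3)
    return SchemePosition(chain, num, ins, scheme)


def compare_positions(a: SchemePosition, b: SchemePosition) -> int:
    """Total order on positions sharing chain and scheme.

    Returns -1 / 0 / +1 for *a* before / equal / after *b*.
    """
    if a.chain != b.chain or a.scheme != b.scheme:
        raise SchemeError(
            f"cannot order positions across chains/schemes: "
            f"{a.label}/{a.scheme} vs {b.label}/{b.scheme}")
    ka, kb = a.sort_key(), b.sort_key()
    return (ka > kb) - (ka < kb)


def sort_positions(positions: Iterable[SchemePosition]) -> list[SchemePosition]:
    """Sort positions of one chain/scheme by :func:`compare_positions`."""
    return sorted(positions, key=SchemePosition.sort_key)


# --------------------------------------------------------------------------
# region catalog
# --------------------------------------------------------------------------

# CDR spans per scheme (inclusive base-number ranges).  These are the
# published CDR definitions of each scheme; "general" is the union of all
# of them expressed on Kabat numbering.
_CDR_SPANS = {
    "kabat": {
        "L": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
        "H": {"CDR1": (31, 35), "CDR2": (50, 65), "CDR3": (95, 102)},
    },
    "chothia": {
        "L": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
        "H": {"CDR1": (26, 32), "CDR2": (52, 56), "CDR3": (95, 102)},
    },
    "consensus_chothia": {
        "L": {"CDR1": (26, 32), "CDR2": (50, 52), "CDR3": (91, 96)},
        "H": {"CDR1": (26, 32), "CDR2": (52, 56), "CDR3": (96, 101)},
    },
    "abm": {
        "L": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
        "H": {"CDR1": (26, 35), "CDR2": (50, 58), "CDR3": (95, 102)},
    },
    "imgt": {
        "L": {"CDR1": (27, 38), "CDR2": (56, 65), "CDR3": (105, 117)},
        "H": {"CDR1": (27, 38), "CDR2": (56, 65), "CDR3": (105, 117)},
    },
    "general": {
        "L": {"CDR1": (24, 34), "CDR2": (50, 56), "CDR3": (89, 97)},
        "H": {"CDR1": (26, 35), "CDR2": (50, 65), "CDR3": (93, 102)},
    },
}

# chain span covered by each catalog (inclusive end of FR4)
_CATALOG_END = {
    "kabat": {"L": 107, "H": 113},
    "chothia": {"L": 107, "H": 113},
    "consensus_chothia": {"L": 107, "H": 113},
    "abm": {"L": 107, "H": 113},
    "imgt": {"L": 128, "H": 128},
    "general": {"L": 107, "H": 113},
}


@dataclass(frozen=True)
class RegionCatalog:
    """Per scheme/chain: the ordered FR/CDR partition of the chain span.

    ``ranges[(scheme, chain)]`` is an ordered list of
    ``(region label, inclusive start, inclusive end)`` covering the chain
    span contiguously; schemes include the five sequence-based schemes
    plus the ``"general"`` union (on Kabat numbering).
    """

    ranges: dict[tuple[str, str], tuple[tuple[str, int, int], ...]]

    def regions(self, scheme: str, chain: str) -> tuple[tuple[str, int, int], ...]:
        try:
            return self.ranges[(scheme, chain)]
        except KeyError:
            raise SchemeError(
                f"no region catalog for scheme {scheme!r}, chain {chain!r}")

    def cdr_spans(self, scheme: str, chain: str) -> dict[str, tuple[int, int]]:
        return {lab: (s, e) for lab, s, e in self.regions(scheme, chain)
                if lab in CDR_REGIONS}

    def span(self, scheme: str, chain: str) -> tuple[int, int]:
        regs = self.regions(scheme, chain)
        return regs[0][1], regs[-1][2]

    def to_records(self) -> list[dict]:
        """Flat export: one record per scheme/chain/region."""
        out = []
        for (scheme, chain), regs in sorted(self.ranges.items()):
            for label, start, end in regs:
                out.append({"scheme": scheme, "chain": chain,
                            "region": label,
                            "start": f"{chain}{start}", "end": f"{chain}{end}"})
        return out


def _build_catalog() -> RegionCatalog:
    ranges: dict[tuple[str, str], tuple[tuple[str, int, int], ...]] = {}
    for scheme in CATALOG_SCHEMES:
        for chain in CHAINS:
            cdrs = _CDR_SPANS[scheme][chain]
            end = _CATALOG_END[scheme][chain]
            (c1s, c1e), (c2s, c2e), (c3s, c3e) = (
                cdrs["CDR1"], cdrs["CDR2"], cdrs["CDR3"])
            regs = (
                ("FR1", 1, c1s - 1),
                ("CDR1", c1s, c1e),
                ("FR2", c1e + 1, c2s - 1),
                ("CDR2", c2s, c2e),
                ("FR3", c2e + 1, c3s - 1),
                ("CDR3", c3s, c3e),
                ("FR4", c3e + 1, end),
            )
            ranges[(scheme, chain)] = regs
    return RegionCatalog(ranges)


@functools.lru_cache(maxsize=1)
def default_catalog() -> RegionCatalog:
    """The packaged FR/CDR region catalog (five schemes + general union)."""
    return _build_catalog()


def region_of(pos: SchemePosition, catalog: Optional[RegionCatalog] = None,
              scheme: Optional[str] = None) -> str:
    """Region label of *pos*; insertion-tagged positions inherit the
    region of their base number.

    ``scheme`` overrides the catalog scheme to look up (used for the
    ``"general"`` union, which lives on Kabat numbering).
    """
    catalog = catalog or default_catalog()
    scheme = scheme or pos.scheme
    for label, start, end in catalog.regions(scheme, pos.chain):
        if start <= pos.number <= end:
            return label
    lo, hi = catalog.span(scheme, pos.chain)
    raise SchemeError(
        f"position {pos.label} outside the {scheme} {pos.chain}-chain "
        f"catalog span {pos.chain}{lo}..{pos.chain}{hi}")


def general_cdr(pos: SchemePosition) -> bool:
    """True iff *pos* (Kabat numbering) lies in the general-CDR union.

    The general CDR encompasses every residue called CDR by any of the
    compared schemes, expressed on Kabat numbering; insertion-tagged
    positions inherit their base number.
    """
    if pos.scheme != "kabat":
        raise SchemeError(
            f"general CDR is defined on Kabat numbering, got {pos.scheme!r}")
    for start, end in _CDR_SPANS["general"][pos.chain].values():
        if start <= pos.number <= end:
            return True
    return False


# --------------------------------------------------------------------------
# inter-scheme equivalence
# --------------------------------------------------------------------------

def _equivalence_rows() -> list[dict[str, str]]:
    with resources.files("igentropy.data").joinpath(
            f"equivalence_{EQUIVALENCE_TABLE_VERSION}.tsv").open() as fh:
        lines = [ln.rstrip("\n") for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


@functools.lru_cache(maxsize=1)
def _equivalence_maps() -> dict[tuple[str, str, str], dict[str, str]]:
    """(chain, scheme, label) -> {target scheme: target label}."""
    maps: dict[tuple[str, str, str], dict[str, str]] = {}
    for row in _equivalence_rows():
        chain = row["chain"]
        for scheme in SCHEMES:
            maps[(chain, scheme, row[scheme])] = row
    return maps


def equivalence_table() -> list[dict[str, str]]:
    """The packaged equivalence table as a list of per-column records."""
    return _equivalence_rows()


def convert_scheme(pos: SchemePosition, target: str) -> SchemePosition:
    """Convert *pos* to the topologically equivalent position in *target*.

    Defined only on the packaged per-chain canonical-column table
    (framework positions and canonical-length CDRs); bijective where
    defined, so converting back returns the input.  A position outside
    the table raises :class:`SchemeError` — it is never guessed.
    """
    if target not in SCHEMES:
        raise SchemeError(f"unknown target scheme {target!r}")
    if target == pos.scheme:
        return pos
    row = _equivalence_maps().get((pos.chain, pos.scheme, pos.label))
    if row is None:
        raise SchemeError(
            f"position {pos.label} ({pos.scheme}) is outside the packaged "
            f"equivalence table and cannot be converted")
    return parse_position_label(row[target], target)
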