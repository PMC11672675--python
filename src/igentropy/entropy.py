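"""Relative-entropy conservation analysis.

The per-position conservation statistic is the relative entropy
(Kullback–Leibler divergence) of the observed amino-acid distribution p
at a position against a reference distribution q::

    RE(x) = sum_i p(x_i) * log( p(x_i) / q(x_i) )

RE is zero iff p equals the reference and grows with divergence from it;
against a diffuse neutral reference, a strongly conserved position
(mass concentrated on one or few residues) yields a high RE.  The log
base defaults to natural (nats); ``base=2`` gives bits.

Two reference modes mirror the two analyses the statistic supports:

* a fixed reference simplex (pooled database composition, or an
  external neutral reference such as proteome-wide usage) for
  within-repertoire conservation profiling;
* another repertoire's positional distributions as the reference
  (:func:`cross_species_profile`) for divergence between species, the
  basis of humanization-hotspot detection.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from igentropy.schemes import (
    RegionCatalog,
    SchemeError,
    SchemePosition,
    convert_scheme,
    default_catalog,
    parse_position_label,
    region_of,
)
from igentropy.frequencies import FrequencyTable, ReferenceDistribution
from igentropy.repio import Repertoire

logger = logging.getLogger(__name__)

NATS = math.e
BITS = 2.0

#: CDR1 pivot positions on IMGT numbering, per light class / heavy chain.
PIVOT_POSITIONS_IMGT = {"kappa": "L29", "lambda": "L30", "heavy": "H30"}

DEFAULT_HOTSPOT_K = 1.65
DEFAULT_PIVOT_CUTOFF = 0.04

_SIMPLEX_TOL = 1e-6


class UnsupportedSupportError(SchemeError):
    """p places mass where the reference q is zero (RE undefined)."""


def _as_q(q: Union[ReferenceDistribution, np.ndarray, Sequence[float]]
          ) -> np.ndarray:
    if isinstance(q, ReferenceDistribution):
        return q.q
    return np.asarray(q, dtype=float)


def relative_entropy(p: Union[np.ndarray, Sequence[float]],
                     q: Union[ReferenceDistribution, np.ndarray,
                              Sequence[float]],
                     base: float = NATS) -> float:
    """RE(p || q) = sum_i p_i log(p_i / q_i), with 0 * log 0 := 0.

    Raises :class:`UnsupportedSupportError` where p_i > 0 with q_i = 0,
    and :class:`SchemeError` for a malformed simplex.
    """
    p = np.asarray(p, dtype=float)
    qv = _as_q(q)
    if p.shape != qv.shape:
        raise SchemeError("p and q must have equal length")
    if (p < 0).any() or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
        raise SchemeError("p is not a probability simplex")
    if ((p > 0) & (qv == 0)).any():
        raise UnsupportedSupportError(
            "p has mass where the reference is zero; use a pseudocount "
            "mode or a reference with full support")
    return float(rel_entr(p, qv).sum() / math.log(base))


@dataclass
class REProfile:
    """Per-position relative entropy with provenance metadata.

    ``values`` is a Series indexed by position label in canonical order;
    ``positions`` the matching :class:`SchemePosition` objects.
    ``skipped`` lists positions omitted for unsupported support in
    pseudocount-off cross-species mode.
    """

    values: pd.Series
    positions: tuple[SchemePosition, ...]
    reference_name: str
    base: float
    scheme: str
    chain: str
    skipped: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.values < -1e-12).any():
            raise SchemeError("relative entropies must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self, catalog: Optional[RegionCatalog] = None
                 ) -> pd.DataFrame:
        catalog = catalog or default_catalog()
        rows = []
        for pos in self.positions:
            try:
                region = region_of(pos, catalog)
            except SchemeError:
                region = "NA"
            rows.append((pos.label, region, float(self.values[pos.label])))
        return pd.DataFrame(rows, columns=["position", "region", "re"])


def re_profile(table: FrequencyTable, ref: ReferenceDistribution,
               base: float = NATS) -> REProfile:
    """One RE value per retained position of the frequency table."""
    values = {}
    for pos in table.positions:
        values[pos.label] = relative_entropy(table.p(pos.label), ref, base)
    series = pd.Series(values, dtype=float)
    return REProfile(values=series, positions=table.positions,
                     reference_name=ref.name, base=base,
                     scheme=table.scheme, chain=table.chain)


def summarize_regions(profile: REProfile,
                      catalog: Optional[RegionCatalog] = None,
                      scheme: Optional[str] = None) -> pd.DataFrame:
    """Mean / median / sample SD / n of RE per region.

    Rows cover each catalog region present, plus the ``all``,
    ``framework`` and ``all_CDR`` aggregates.  A region with no profiled
    positions is reported with n = 0 and absent (NaN) statistics; SD
    uses the n-1 denominator and is NaN for n < 2.
    """
    catalog = catalog or default_catalog()
    scheme = scheme or profile.scheme
    member: dict[str, list[float]] = {}
    for pos in profile.positions:
        region = region_of(pos, catalog, scheme=scheme)
        member.setdefault(region, []).append(float(profile.values[pos.label]))

    all_vals = [v for vals in member.values() for v in vals]
    fr_vals = [v for reg, vals in member.items() if reg.startswith("FR")
               for v in vals]
    cdr_vals = [v for reg, vals in member.items() if reg.startswith("CDR")
                for v in vals]

    def stats(vals: list[float]) -> list:
        n = len(vals)
        if n == 0:
            return [np.nan, np.nan, np.nan, 0]
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if n >= 2 else np.nan
        return [float(arr.mean()), float(np.median(arr)), sd, n]

    labels = [lab for lab, _s, _e in catalog.regions(scheme, profile.chain)]
    rows = {lab: stats(member.get(lab, [])) for lab in labels}
    rows["all"] = stats(all_vals)
    rows["framework"] = stats(fr_vals)
    rows["all_CDR"] = stats(cdr_vals)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "median", "sd", "n"])
    out.index.name = "region"
    out["n"] = out["n"].astype(int)
    return out


@dataclass(frozen=True)
class FiveNumberSummary:
    """Box-plot statistics: whiskers at the most extreme data points
    within 1.5 * IQR of the box; points beyond are outliers."""

    lower_whisker: float
    q1: float
    median: float
    q3: float
    upper_whisker: float
    outliers: tuple[float, ...]


def five_number_summary(values: Sequence[float]) -> FiveNumberSummary:
    """Quartiles (linear interpolation), 1.5*IQR whiskers, and outliers."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise SchemeError("five_number_summary of an empty list")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return FiveNumberSummary(
        lower_whisker=float(inside.min()), q1=float(q1), median=float(med),
        q3=float(q3), upper_whisker=float(inside.max()),
        outliers=tuple(float(v) for v in np.sort(outliers)))


def cross_species_profile(table_a: FrequencyTable, table_b: FrequencyTable,
                          base: float = NATS,
                          pseudocount: Optional[float] = None) -> REProfile:
    """RE of table_a's positional distributions against table_b's.

    Evaluated on positions retained in both tables; table_b plays the
    reference q (e.g. mouse as reference when scoring human divergence).
    With ``pseudocount`` set, alpha is added to all 20 counts on *both*
    sides before normalizing; otherwise a position where p has mass
    outside q's support is skipped and logged (listed in ``skipped``).
    """
    if (table_a.scheme, table_a.chain) != (table_b.scheme, table_b.chain):
        raise SchemeError("cross-species tables must share scheme and chain")
    shared = [pos for pos in table_a.positions
              if pos.label in table_b.counts.index]
    if not shared:
        raise SchemeError("no shared retained positions between the tables")
    values: dict[str, float] = {}
    skipped: list[str] = []
    kept: list[SchemePosition] = []
    for pos in shared:
        ca = table_a.counts.loc[pos.label].to_numpy(dtype=float)
        cb = table_b.counts.loc[pos.label].to_numpy(dtype=float)
        if pseudocount is not None:
            ca = ca + pseudocount
            cb = cb + pseudocount
        p = ca / ca.sum()
        q = cb / cb.sum()
        try:
            values[pos.label] = relative_entropy(p, q, base)
            kept.append(pos)
        except UnsupportedSupportError:
            logger.info("position %s skipped: residues in a absent from b "
                        "(enable pseudocounts to include it)", pos.label)
            skipped.append(pos.label)
    ref_name = "cross_species" if pseudocount is None else (
        f"cross_species(alpha={pseudocount})")
    return REProfile(values=pd.Series(values, dtype=float),
                     positions=tuple(kept), reference_name=ref_name,
                     base=base, scheme=table_a.scheme, chain=table_a.chain,
                     skipped=tuple(skipped))


@dataclass
class HotspotReport:
    """Positions whose RE strictly exceeds mean + k * SD of their group.

    ``thresholds`` has one row per group (mean, sd, n, threshold);
    ``flagged`` one row per flagged position (position, group, re,
    threshold).  Groups with n < 2 have an undefined SD and are skipped
    with a warning.
    """

    k: float
    by: str
    thresholds: pd.DataFrame
    flagged: pd.DataFrame


def detect_hotspots(profile: REProfile,
                    catalog: Optional[RegionCatalog] = None,
                    k: float = DEFAULT_HOTSPOT_K,
                    by: str = "chain") -> HotspotReport:
    """Flag positions with RE > mean + k * SD of their group.

    ``by="chain"`` (default) uses one group per profile — the whole
    chain's positions set the mean and SD, so a handful of strongly
    divergent positions inflate the dispersion and only they clear the
    threshold.  ``by="region"`` computes thresholds per catalog region
    instead; note that a region containing no truly divergent position
    then flags its own sampling-noise maxima at a roughly constant rate,
    so the chain-wide threshold is the default for hotspot screening.
    The inequality is strict, so a constant group flags nothing.
    """
    catalog = catalog or default_catalog()
    if by not in ("chain", "region"):
        raise SchemeError(f"unknown grouping {by!r}")
    groups: dict[str, list[SchemePosition]] = {}
    for pos in profile.positions:
        group = "chain" if by == "chain" else region_of(pos, catalog)
        groups.setdefault(group, []).append(pos)

    thr_rows = []
    flag_rows = []
    for group, members in groups.items():
        vals = np.array([profile.values[p.label] for p in members])
        n = len(vals)
        if n < 2:
            warnings.warn(
                f"hotspot group {group!r} has n={n} < 2; SD undefined, "
                f"group skipped", stacklevel=2)
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        threshold = mean + k * sd
        thr_rows.append((group, mean, sd, n, threshold))
        for pos, v in zip(members, vals):
            if v > threshold:
                flag_rows.append((pos.label, group, float(v), threshold))
    thresholds = pd.DataFrame(
        thr_rows, columns=["group", "mean", "sd", "n", "threshold"]
    ).set_index("group")
    flagged = pd.DataFrame(
        flag_rows, columns=["position", "group", "re", "threshold"])
    return HotspotReport(k=k, by=by, thresholds=thresholds, flagged=flagged)


@dataclass
class PivotReport:
    """Amino-acid distributions at the CDR1 pivot positions per stratum.

    ``distributions`` maps stratum ("kappa", "lambda", "heavy") to a
    Series of frequencies over occupied sequences, with entries below
    the display cutoff aggregated into ``"other"``; ``counts`` gives the
    occupied-sequence count per stratum and ``positions`` the pivot
    label used in the repertoire's scheme.
    """

    distributions: dict[str, pd.Series]
    counts: dict[str, int]
    positions: dict[str, str]
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum, dist in self.distributions.items():
            for aa, freq in dist.items():
                rows.append((stratum, self.positions[stratum], aa,
                             float(freq)))
        return pd.DataFrame(
            rows, columns=["stratum", "position", "amino_acid", "frequency"])


def pivot_distribution(rep: Repertoire,
                       table: Optional[FrequencyTable] = None,
                       cutoff: float = DEFAULT_PIVOT_CUTOFF) -> PivotReport:
    """Residue distributions at the CDR1 pivot point, stratified by class.

    The pivot point is the structurally conserved CDR1 residue splitting
    the loop in two — IMGT L29 in kappa light chains, L30 in lambda, H30
    in heavy chains — converted to the repertoire's scheme through the
    packaged equivalence table.  Frequencies below ``cutoff`` (default
    4%) are aggregated into ``"other"``; a stratum with no occupied
    sequence at its pivot is reported empty.  ``table`` optionally
    restricts counting to pivots retained by its occupancy filter.
    """
    strata = (("kappa", "lambda") if rep.chain == "L" else ("heavy",))
    positions: dict[str, str] = {}
    for stratum in strata:
        imgt_pos = parse_position_label(PIVOT_POSITIONS_IMGT[stratum], "imgt")
        positions[stratum] = convert_scheme(imgt_pos, rep.scheme).label
    if table is not None:
        for stratum, label in positions.items():
            if label not in table.counts.index:
                logger.info("pivot %s (%s) not retained by the occupancy "
                            "filter", label, stratum)

    distributions: dict[str, pd.Series] = {}
    counts: dict[str, int] = {}
    for stratum in strata:
        label = positions[stratum]
        tallies: dict[str, int] = {}
        for rec in rep.records:
            if rep.chain == "L" and rec.light_class != stratum:
                continue
            for pos, aa in rec.occupied():
                if pos.label == label:
                    tallies[aa] = tallies.get(aa, 0) + 1
                    break
        total = sum(tallies.values())
        counts[stratum] = total
        if total == 0:
            distributions[stratum] = pd.Series(dtype=float)
            continue
        freqs = pd.Series(tallies, dtype=float).sort_index() / total
        if cutoff > 0:
            small = freqs[freqs < cutoff]
            freqs = freqs[freqs >= cutoff]
            if len(small):
                freqs["other"] = float(small.sum())
        distributions[stratum] = freqs
    return PivotReport(distributions=distributions, counts=counts,
                       positions=positions, cutoff=cutoff)
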