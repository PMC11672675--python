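"""Per-position amino-acid frequencies, occupancy filtering, and
region-level compositions.

Occupancy of a position is the fraction of sequences in the repertoire
carrying a canonical residue there.  Positions with occupancy strictly
below the threshold (default 30%) are discarded — a position occupied by
exactly 30% of sequences is retained.  Frequencies are computed over the
*occupied* sequences at each position: schemes assign no number where a
residue is absent, so absence is not an observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from igentropy.schemes import (
    AMINO_ACIDS,
    RegionCatalog,
    SchemeError,
    SchemePosition,
    default_catalog,
    region_of,
    general_cdr,
)
from igentropy.repio import Repertoire

DEFAULT_MIN_OCCUPANCY = 0.30

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ReferenceDistribution:
    """A named 20-amino-acid simplex q used as the RE reference."""

    name: str
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (20,):
            raise SchemeError("reference must be a 20-vector over amino acids")
        if (q < 0).any():
            raise SchemeError("reference entries must be non-negative")
        if abs(q.sum() - 1.0) > 1e-9:
            raise SchemeError("reference must sum to 1 within 1e-9")
        object.__setattr__(self, "q", q)

    def as_series(self) -> pd.Series:
        return pd.Series(self.q, index=list(AMINO_ACIDS), name=self.name)

    @classmethod
    def uniform(cls) -> "ReferenceDistribution":
        return cls(name="uniform", q=np.full(20, 1 / 20))

    @classmethod
    def from_mapping(cls, name: str, weights: dict) -> "ReferenceDistribution":
        q = np.zeros(20)
        for aa, w in weights.items():
            q[_AA_INDEX[aa]] = w
        return cls(name=name, q=q / q.sum())


@dataclass
class FrequencyTable:
    """Per-position amino-acid counts and frequencies with occupancy.

    ``counts`` is a (position label x 20) integer DataFrame over the
    retained positions in canonical order; ``positions`` holds the
    matching :class:`SchemePosition` objects.  ``discarded`` lists
    ``(label, occupancy)`` for positions dropped by the occupancy filter.
    """

    counts: pd.DataFrame
    positions: tuple[SchemePosition, ...]
    n_sequences: int
    scheme: str
    chain: str
    min_occupancy: float
    discarded: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    @property
    def occupancy(self) -> pd.Series:
        return self.counts.sum(axis=1) / self.n_sequences

    @property
    def frequencies(self) -> pd.DataFrame:
        """Row-normalized frequencies p over occupied sequences."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    def p(self, label: str) -> np.ndarray:
        """The frequency simplex at one retained position."""
        row = self.counts.loc[label].to_numpy(dtype=float)
        return row / row.sum()

    def position_by_label(self, label: str) -> SchemePosition:
        for pos in self.positions:
            if pos.label == label:
                return pos
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        """Export table: position, occupancy, 20 freq + 20 count columns."""
        freq = self.frequencies.add_prefix("freq_")
        cnt = self.counts.add_prefix("count_")
        out = pd.concat([self.occupancy.rename("occupancy"), freq, cnt],
                        axis=1)
        out.insert(0, "position", out.index)
        return out.reset_index(drop=True)


def build_frequency_table(rep: Repertoire,
                          min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
                          ) -> FrequencyTable:
    """Count residues per position and apply the occupancy filter.

    Retains exactly the positions with occupancy >= ``min_occupancy``
    (strict "< threshold discarded" rule); frequencies are over occupied
    sequences only.  Raises :class:`SchemeError` on an empty repertoire.
    """
    if len(rep) == 0:
        raise SchemeError("cannot build a frequency table from an empty "
                          "repertoire")
    if not 0.0 <= min_occupancy <= 1.0:
        raise SchemeError("min_occupancy must lie in [0, 1]")

    counts: dict[SchemePosition, np.ndarray] = {}
    for rec in rep.records:
        for pos, aa in rec.occupied():
            vec = counts.get(pos)
            if vec is None:
                vec = counts[pos] = np.zeros(20, dtype=np.int64)
            vec[_AA_INDEX[aa]] += 1

    n = len(rep)
    ordered = sorted(counts, key=SchemePosition.sort_key)
    kept, dropped = [], []
    for pos in ordered:
        occ = counts[pos].sum() / n
        if occ < min_occupancy:
            dropped.append((pos.label, occ))
        else:
            kept.append(pos)
    frame = pd.DataFrame(
        [counts[pos] for pos in kept],
        index=[pos.label for pos in kept],
        columns=list(AMINO_ACIDS), dtype=np.int64)
    return FrequencyTable(counts=frame, positions=tuple(kept),
                          n_sequences=n, scheme=rep.scheme, chain=rep.chain,
                          min_occupancy=min_occupancy,
                          discarded=tuple(dropped))


def pooled_reference(source: Union[Repertoire, FrequencyTable,
                                   Sequence[FrequencyTable]],
                     min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
                     name: str = "pooled") -> ReferenceDistribution:
    """Aggregate amino-acid composition of the repertoire as reference q.

    The pooled reference is the normalized sum of residue counts over all
    retained positions and sequences — the database-wide amino-acid usage
    of the variable domains, used as the neutral reference state.
    Accepts a Repertoire (a frequency table is built first), a single
    FrequencyTable, or several tables whose counts are pooled.
    """
    if isinstance(source, Repertoire):
        tables: list[FrequencyTable] = [
            build_frequency_table(source, min_occupancy)]
    elif isinstance(source, FrequencyTable):
        tables = [source]
    else:
        tables = list(source)
    if not tables:
        raise SchemeError("no input to pool")
    total = np.zeros(20, dtype=float)
    for t in tables:
        total += t.counts.to_numpy(dtype=float).sum(axis=0)
    if total.sum() <= 0:
        raise SchemeError("no residues counted; cannot pool a reference")
    return ReferenceDistribution(name=name, q=total / total.sum())


def composition_by_region(table: FrequencyTable,
                          catalog: Optional[RegionCatalog] = None,
                          grouping: str = "general_cdr") -> pd.DataFrame:
    """Aggregate amino-acid composition per region group.

    Groupings:

    * ``"general_cdr"`` — two rows, ``FR`` and ``CDR``, split by the
      general-CDR union (requires a Kabat-numbered table);
    * ``"framework"`` — one row per framework region plus ``FR_all``;
    * ``"per_cdr_loop"`` — one row per CDR loop plus ``CDR_all`` (the
      table scheme's own CDR definition).

    Compositions are aggregated by raw counts (never by averaging
    per-position frequencies).  A group with no occupied positions is
    reported with ``n_residues = 0`` and NaN frequencies.
    """
    catalog = catalog or default_catalog()
    if grouping not in ("general_cdr", "framework", "per_cdr_loop"):
        raise SchemeError(f"unknown grouping {grouping!r}")

    group_counts: dict[str, np.ndarray] = {}

    def add(group: str, vec: np.ndarray) -> None:
        group_counts.setdefault(group, np.zeros(20))
        group_counts[group] += vec

    if grouping == "general_cdr":
        if table.scheme != "kabat":
            raise SchemeError(
                "general-CDR grouping requires Kabat-expressed positions")
        group_counts = {"FR": np.zeros(20), "CDR": np.zeros(20)}
        for pos in table.positions:
            vec = table.counts.loc[pos.label].to_numpy(dtype=float)
            add("CDR" if general_cdr(pos) else "FR", vec)
    else:
        if grouping == "framework":
            group_counts = {f"FR{i}": np.zeros(20) for i in range(1, 5)}
        else:
            group_counts = {f"CDR{i}": np.zeros(20) for i in range(1, 4)}
        for pos in table.positions:
            region = region_of(pos, catalog)
            vec = table.counts.loc[pos.label].to_numpy(dtype=float)
            if grouping == "framework" and region.startswith("FR"):
                add(region, vec)
            elif grouping == "per_cdr_loop" and region.startswith("CDR"):
                add(region, vec)
        if grouping == "framework":
            add("FR_all", sum(group_counts[f"FR{i}"] for i in range(1, 5)))
        else:
            add("CDR_all", sum(group_counts[f"CDR{i}"] for i in range(1, 4)))

    rows = []
    for group, vec in group_counts.items():
        total = vec.sum()
        freqs = vec / total if total > 0 else np.full(20, np.nan)
        rows.append([group, int(total)] + list(freqs))
    out = pd.DataFrame(rows, columns=["group", "n_residues"]
                       + list(AMINO_ACIDS))
    return out.set_index("group")
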