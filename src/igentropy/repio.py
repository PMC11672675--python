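"""Reading and writing numbered repertoires and reference distributions.

The on-disk repertoire format is a long-format tab-separated table, one
row per residue, with a required header::

    sequence_id  species  chain  light_class  scheme  position  amino_acid

All records in one file share chain and scheme.  Non-canonical residue
symbols (X, B, Z, gaps, ...) are treated as *unoccupied* at that position
rather than rejected: schemes simply assign no number where a residue is
absent, so absence is not an observation.  Exact duplicate sequences
(identical residue lists, regardless of id or species) are collapsed on
load with a logged count, so a loaded repertoire contains non-identical
sequences only.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

import numpy as np
import pandas as pd

from igentropy.schemes import (
    AMINO_ACIDS,
    CHAINS,
    SCHEMES,
    SchemeError,
    SchemePosition,
    parse_position_label,
)

logger = logging.getLogger(__name__)

LIGHT_CLASSES = ("kappa", "lambda", "not_applicable")

_COLUMNS = ("sequence_id", "species", "chain", "light_class", "scheme",
            "position", "amino_acid")


@dataclass(frozen=True)
class SequenceRecord:
    """One numbered variable-domain sequence.

    ``residues`` is an ordered tuple of ``(SchemePosition, one-letter
    amino acid)`` pairs, strictly increasing in position order with no
    duplicates.  Heavy chains carry ``light_class = "not_applicable"``.
    """

    id: str
    species: str
    chain: str
    light_class: str
    scheme: str
    residues: tuple[tuple[SchemePosition, str], ...]

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise SchemeError(f"unknown chain {self.chain!r}")
        if self.scheme not in SCHEMES:
            raise SchemeError(f"unknown scheme {self.scheme!r}")
        if self.light_class not in LIGHT_CLASSES:
            raise SchemeError(f"unknown light class {self.light_class!r}")
        if (self.light_class == "not_applicable") != (self.chain == "H"):
            raise SchemeError(
                f"record {self.id!r}: light_class must be 'not_applicable' "
                f"iff chain is H")
        keys = [p.sort_key() for p, _ in self.residues]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise SchemeError(
                f"record {self.id!r}: residue positions must be strictly "
                f"increasing with no duplicates")
        for pos, _aa in self.residues:
            if pos.chain != self.chain or pos.scheme != self.scheme:
                raise SchemeError(
                    f"record {self.id!r}: position {pos.label} does not "
                    f"match record chain/scheme")

    def residue_signature(self) -> tuple[tuple[str, str], ...]:
        """Hashable identity used for duplicate collapse (residues only)."""
        return tuple((p.label, aa) for p, aa in self.residues)

    def occupied(self) -> tuple[tuple[SchemePosition, str], ...]:
        """Residues with a canonical amino acid (the countable ones)."""
        return tuple((p, aa) for p, aa in self.residues if aa in AMINO_ACIDS)


@dataclass
class Repertoire:
    """A set of numbered sequences sharing chain and scheme."""

    records: tuple[SequenceRecord, ...]
    chain: str
    scheme: str
    provenance: str = "unspecified"
    duplicates_collapsed: int = 0

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise SchemeError("record ids must be unique within a repertoire")
        for r in self.records:
            if r.chain != self.chain or r.scheme != self.scheme:
                raise SchemeError(
                    f"record {r.id!r} does not share the repertoire "
                    f"chain/scheme ({self.chain}, {self.scheme})")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame (one row per residue, canonical order)."""
        rows = []
        for rec in self.records:
            for pos, aa in rec.residues:
                rows.append((rec.id, rec.species, rec.chain, rec.light_class,
                             rec.scheme, pos.label, aa))
        return pd.DataFrame(rows, columns=list(_COLUMNS))


def _as_text_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_numbered_table(source: Union[str, TextIO],
                        provenance: str = "file") -> Repertoire:
    """Read a long-format numbered-sequence table into a Repertoire.

    Rows within a sequence need not be sorted (they are sorted on load);
    exact duplicate sequences are collapsed with a logged count.  Raises
    :class:`SchemeError` on mixed chains or schemes, malformed position
    labels, or duplicate (id, position) rows.
    """
    fh = _as_text_stream(source)
    df = pd.read_csv(fh, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise SchemeError(f"missing required columns: {sorted(missing)}")
    if df.empty:
        raise SchemeError("empty repertoire table")

    schemes = df["scheme"].unique()
    chains = df["chain"].unique()
    if len(schemes) > 1:
        raise SchemeError(f"mixed schemes in one file: {sorted(schemes)}")
    if len(chains) > 1:
        raise SchemeError(f"mixed chains in one file: {sorted(chains)}")
    scheme, chain = schemes[0], chains[0]

    records: list[SequenceRecord] = []
    seen_signatures: set[tuple] = set()
    collapsed = 0
    for seq_id, grp in df.groupby("sequence_id", sort=True):
        if grp["position"].duplicated().any():
            dups = grp.loc[grp["position"].duplicated(), "position"].tolist()
            raise SchemeError(
                f"duplicate (id, position) rows for {seq_id!r}: {dups}")
        residues = [(parse_position_label(p, scheme), aa)
                    for p, aa in zip(grp["position"], grp["amino_acid"])]
        residues.sort(key=lambda t: t[0].sort_key())
        rec = SequenceRecord(
            id=str(seq_id),
            species=grp["species"].iloc[0],
            chain=chain,
            light_class=grp["light_class"].iloc[0],
            scheme=scheme,
            residues=tuple(residues),
        )
        sig = rec.residue_signature()
        if sig in seen_signatures:
            collapsed += 1
            continue
        seen_signatures.add(sig)
        records.append(rec)
    if collapsed:
        logger.info("collapsed %d duplicate sequence(s) on load", collapsed)
    return Repertoire(records=tuple(records), chain=chain, scheme=scheme,
                      provenance=provenance, duplicates_collapsed=collapsed)


def write_numbered_table(rep: Repertoire, sink: TextIO,
                         header_comment: Optional[str] = None) -> None:
    """Write a Repertoire in canonical sorted order (byte-stable).

    ``read_numbered_table(write_numbered_table(rep))`` reproduces the
    repertoire exactly (records sorted by id, residues by position).
    """
    if header_comment:
        for line in header_comment.splitlines():
            sink.write(f"# {line}\n")
    sink.write("\t".join(_COLUMNS) + "\n")
    for rec in sorted(rep.records, key=lambda r: r.id):
        for pos, aa in rec.residues:
            sink.write(f"{rec.id}\t{rec.species}\t{rec.chain}\t"
                       f"{rec.light_class}\t{rec.scheme}\t{pos.label}\t{aa}\n")


def read_reference_distribution(source: Union[str, TextIO],
                                name: str = "reference"):
    """Read a 20-row (amino acid, weight) table as a reference simplex.

    Weights need not be normalized; all 20 canonical amino acids must be
    present exactly once with non-negative weights summing to > 0.
    """
    from igentropy.frequencies import ReferenceDistribution

    fh = _as_text_stream(source)
    df = pd.read_csv(fh, sep="\t", comment="#", dtype={0: str},
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise SchemeError("reference table needs (amino_acid, weight) columns")
    aa_col, w_col = df.columns[0], df.columns[1]
    aas = df[aa_col].tolist()
    if sorted(aas) != sorted(AMINO_ACIDS):
        raise SchemeError(
            "reference table must contain each of the 20 canonical amino "
            f"acids exactly once; got {sorted(aas)}")
    weights = pd.to_numeric(df[w_col]).to_numpy(dtype=float)
    if (weights < 0).any():
        raise SchemeError("reference weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise SchemeError("reference weights are all zero")
    q = np.zeros(len(AMINO_ACIDS))
    for aa, w in zip(aas, weights):
        q[AMINO_ACIDS.index(aa)] = w / total
    return ReferenceDistribution(name=name, q=q)


def records_from_arrays(ids: Iterable[str], species: str, chain: str,
                        light_classes: Iterable[str], scheme: str,
                        positions: list[SchemePosition],
                        residue_matrix: np.ndarray,
                        occupancy_mask: np.ndarray) -> list[SequenceRecord]:
    """Assemble records from a (n_sequences x n_positions) residue matrix.

    ``residue_matrix`` holds indices into :data:`AMINO_ACIDS`;
    ``occupancy_mask`` marks which entries exist.  Used by the synthetic
    generator; positions must already be in canonical order.
    """
    out = []
    aa = np.array(list(AMINO_ACIDS))
    for i, (sid, lclass) in enumerate(zip(ids, light_classes)):
        occ = occupancy_mask[i]
        residues = tuple(
            (positions[j], aa[residue_matrix[i, j]])
            for j in np.nonzero(occ)[0])
        out.append(SequenceRecord(id=sid, species=species, chain=chain,
                                  light_class=lclass, scheme=scheme,
                                  residues=residues))
    return out
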