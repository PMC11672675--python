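"""2D consensus-map construction on the Aho grid.

The consensus map is the data layer behind a 2D spatial view of
variable-domain conservation: one cell per retained position on the Aho
numbering grid, carrying the modal (consensus) residue and its
frequency, the beta-strand label of the Gelfand description (A, A', A'',
B, C, C', C'', D, E, F, G), a flag for the Aho structurally conserved
C-alpha core, and the IMGT CDR membership flag.  Strand and core spans
ship as an approximate versioned annotation table; rendering (colors,
backbone hydrogen-bond arrows) is left to external plotting.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Optional, TextIO

import pandas as pd

from igentropy.schemes import (
    ANNOTATION_TABLE_VERSION,
    SchemeError,
    SchemePosition,
    convert_scheme,
    default_catalog,
    region_of,
)
from igentropy.frequencies import FrequencyTable


@functools.lru_cache(maxsize=1)
def _annotation() -> pd.DataFrame:
    with resources.files("igentropy.data").joinpath(
            f"strand_annotation_{ANNOTATION_TABLE_VERSION}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def strand_of(chain: str, aho_number: int) -> Optional[str]:
    """Gelfand strand label at an Aho position, or None (loop/terminus)."""
    ann = _annotation()
    hit = ann[(ann["chain"] == chain) & (ann["kind"] == "strand")
              & (ann["aho_start"] <= aho_number)
              & (aho_number <= ann["aho_end"])]
    return None if hit.empty else str(hit["label"].iloc[0])


def in_core(chain: str, aho_number: int) -> bool:
    """Whether an Aho position lies in the conserved C-alpha core."""
    ann = _annotation()
    hit = ann[(ann["chain"] == chain) & (ann["kind"] == "core")
              & (ann["aho_start"] <= aho_number)
              & (aho_number <= ann["aho_end"])]
    return not hit.empty


@dataclass(frozen=True)
class ConsensusCell:
    """One grid cell: Aho position, consensus residue and top frequency,
    strand label, IMGT CDR flag, and conserved-core flag."""

    position: SchemePosition  # aho scheme
    residue: str
    top_frequency: float
    strand: Optional[str]
    cdr_flag: Optional[str]
    core_flag: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.top_frequency <= 1.0:
            raise SchemeError("top frequency must lie in (0, 1]")


@dataclass
class ConsensusMap:
    """Ordered consensus cells for one chain on the Aho grid."""

    chain: str
    cells: tuple[ConsensusCell, ...]
    skipped: tuple[str, ...]
    annotation_version: str = ANNOTATION_TABLE_VERSION

    def __len__(self) -> int:
        return len(self.cells)


def consensus_calls(table: FrequencyTable) -> list[tuple[SchemePosition,
                                                         str, float]]:
    """Modal amino acid and its frequency per retained position.

    Exact ties are broken alphabetically by one-letter code, so the call
    is deterministic.
    """
    if len(table.positions) == 0:
        raise SchemeError("empty frequency table")
    calls = []
    for pos in table.positions:
        p = table.frequencies.loc[pos.label]
        # idxmax on the alphabetically ordered columns breaks ties to the
        # alphabetically first residue
        residue = p.idxmax()
        calls.append((pos, str(residue), float(p[residue])))
    return calls


def build_map(calls: list[tuple[SchemePosition, str, float]],
              chain: Optional[str] = None) -> ConsensusMap:
    """Assemble consensus calls into an annotated Aho-grid map.

    Calls on any scheme are converted to Aho positions through the
    packaged equivalence table; positions outside the table are reported
    in ``skipped``, never silently dropped.  CDR flags come from the
    IMGT region catalog (via conversion to IMGT numbering), strand and
    core flags from the packaged annotation.
    """
    if not calls:
        raise SchemeError("no consensus calls to map")
    chain = chain or calls[0][0].chain
    catalog = default_catalog()
    cells = []
    skipped = []
    for pos, residue, freq in calls:
        if pos.chain != chain:
            raise SchemeError(
                f"call at {pos.label} does not match map chain {chain}")
        try:
            aho_pos = convert_scheme(pos, "aho")
            imgt_pos = convert_scheme(pos, "imgt")
        except SchemeError:
            skipped.append(pos.label)
            continue
        region = region_of(imgt_pos, catalog, scheme="imgt")
        cdr_flag = region if region.startswith("CDR") else None
        cells.append(ConsensusCell(
            position=aho_pos, residue=residue, top_frequency=freq,
            strand=strand_of(chain, aho_pos.number),
            cdr_flag=cdr_flag,
            core_flag=in_core(chain, aho_pos.number)))
    cells.sort(key=lambda c: c.position.sort_key())
    return ConsensusMap(chain=chain, cells=tuple(cells),
                        skipped=tuple(skipped))


def export_map(cmap: ConsensusMap, sink: TextIO) -> None:
    """Write the map as a deterministic TSV suitable for plotting."""
    sink.write("position\tresidue\ttop_frequency\tstrand\tcdr_flag\t"
               "core_flag\n")
    for cell in cmap.cells:
        strand = cell.strand or ""
        cdr = cell.cdr_flag or ""
        sink.write(f"{cell.position.label}\t{cell.residue}\t"
                   f"{cell.top_frequency:.6f}\t{strand}\t{cdr}\t"
                   f"{str(cell.core_flag).lower()}\n")
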