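"""Aho-grid consensus maps.

Converts the per-position consensus calls of each human repertoire onto
the Aho numbering grid and annotates each cell with its Gelfand strand
label, conserved-core flag and IMGT CDR flag — the data layer for a 2D
conservation map.  The conserved cysteines surface as near-unanimous 'C'
cells at Aho 23 and 106 inside annotated strands, and the planted
RFSGSXSG strand reads back from the light-chain consensus.

Reads results/data/; writes results/consensus/.
"""

from pathlib import Path

import igentropy as ig

IN = Path("results/data")
OUT = Path("results/consensus")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for chain in ("L", "H"):
        with (IN / f"human_{chain}_kabat.tsv").open() as fh:
            rep = ig.read_numbered_table(fh)
        table = ig.build_frequency_table(rep)
        calls = ig.consensus_calls(table)
        cmap = ig.build_map(calls, chain=chain)
        with (OUT / f"human_{chain}_consensus_map.tsv").open("w") as fh:
            ig.export_map(cmap, fh)
        n_core = sum(c.core_flag for c in cmap.cells)
        n_cdr = sum(c.cdr_flag is not None for c in cmap.cells)
        print(f"{chain} chain: {len(cmap.cells)} cells "
              f"({n_core} core, {n_cdr} IMGT-CDR), "
              f"{len(cmap.skipped)} unconvertible position(s) reported: "
              f"{list(cmap.skipped)}")
        cys = [c for c in cmap.cells if c.position.number in (23, 106)]
        for c in cys:
            print(f"  {c.position.label}: consensus {c.residue} "
                  f"{c.top_frequency:.0%}, strand {c.strand}, "
                  f"core {c.core_flag}")
        if chain == "L":
            kabat_61_68 = [ig.convert_scheme(
                ig.parse_position_label(f"L{i}", "kabat"), "aho").label
                for i in range(61, 69)]
            by_label = {c.position.label: c.residue for c in cmap.cells}
            strand = "".join(by_label[lab] for lab in kabat_61_68)
            print(f"  conserved light strand consensus: {strand}")


if __name__ == "__main__":
    main()
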