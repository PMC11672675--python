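"""Regenerate the versioned data tables shipped inside igentropy.

Writes, under src/igentropy/data/:

* ``equivalence_v1.tsv``  — the per-chain canonical-column inter-scheme
  equivalence table (one row per column of a canonical-length variable
  domain, one label column per scheme).
* ``strand_annotation_v1.tsv`` — approximate Gelfand beta-strand spans
  and Aho conserved-core spans on the Aho grid.
* ``yeast_reference_v1.tsv`` — approximate S. cerevisiae proteome
  amino-acid composition, the package's default neutral reference.

The equivalence table is a curated segment model, monotone and bijective
per scheme, honoring the published anchor correspondences (conserved
Cys/Trp, the CDR1 pivot columns, the IMGT 105/106 <-> Kabat H93/H94
CDR3 start, and the RFSGSXSG light-chain strand at IMGT L75-L82).
Run from the repository root:  python scripts/build_tables.py
"""

from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "igentropy" / "data"

SCHEMES = ("kabat", "chothia", "consensus_chothia", "abm", "imgt", "aho")


def rng(a, b):
    return [str(i) for i in range(a, b + 1)]


def light_columns():
    kabat = (rng(1, 23)
             + ["24", "25", "26", "27", "27A", "27B"] + rng(28, 34)
             + rng(35, 49) + rng(50, 56) + rng(57, 88) + rng(89, 97)
             + rng(98, 107))
    chothia = (rng(1, 23)
               + rng(24, 30) + ["30A", "30B"] + rng(31, 34)
               + rng(35, 49) + rng(50, 56) + rng(57, 88) + rng(89, 97)
               + rng(98, 107))
    imgt = (rng(1, 23) + rng(24, 36) + rng(39, 53) + rng(56, 62)
            + rng(66, 69) + rng(75, 82) + rng(85, 104)
            + rng(105, 109) + rng(114, 117) + rng(118, 127))
    aho = (rng(1, 23) + rng(24, 36) + rng(43, 57) + rng(58, 64)
           + rng(75, 106) + rng(107, 115) + rng(139, 148))
    assert len(kabat) == len(chothia) == len(imgt) == len(aho) == 109
    return {"kabat": kabat, "chothia": chothia,
            "consensus_chothia": chothia, "abm": chothia,
            "imgt": imgt, "aho": aho}


def heavy_columns():
    straight = rng(1, 113)
    imgt = (rng(1, 9) + rng(11, 23) + rng(24, 31) + rng(32, 36)
            + rng(39, 52)
            + rng(53, 60) + ["60.1", "60.2", "60.3"] + rng(61, 65)
            + rng(66, 71) + rng(84, 104) + ["105", "106"]
            + rng(107, 110) + rng(114, 117) + rng(118, 128))
    aho = (rng(1, 9) + rng(11, 23) + rng(24, 31) + rng(32, 36)
           + rng(43, 56) + rng(57, 72) + rng(80, 106) + ["107", "108"]
           + rng(109, 116) + rng(139, 149))
    assert len(imgt) == len(aho) == 113, (len(imgt), len(aho))
    return {"kabat": straight, "chothia": straight,
            "consensus_chothia": straight, "abm": straight,
            "imgt": imgt, "aho": aho}


ANCHORS = [  # (chain, kabat label, imgt label, aho label or None)
    ("L", "L23", "L23", "L23"),      # conserved Cys
    ("L", "L27B", "L29", None),      # kappa CDR1 pivot column
    ("L", "L61", "L75", None),       # RFSGSXSG strand start
    ("L", "L68", "L82", None),       # RFSGSXSG strand end
    ("L", "L88", "L104", "L106"),    # conserved Cys
    ("H", "H22", "H23", "H23"),      # conserved Cys
    ("H", "H29", "H30", None),       # HCDR1 pivot column
    ("H", "H93", "H105", None),      # general-CDR3 start = IMGT CDR3 start
    ("H", "H92", "H104", "H106"),    # conserved Cys
]


def build_equivalence():
    rows = []
    for chain, cols in (("L", light_columns()), ("H", heavy_columns())):
        n = len(cols["kabat"])
        for i in range(n):
            rows.append({"chain": chain,
                         **{s: chain + cols[s][i] for s in SCHEMES}})
    # anchor checks
    by = {(r["chain"], r["kabat"]): r for r in rows}
    for chain, kab, imgt, aho in ANCHORS:
        r = by[(chain, kab)]
        assert r["imgt"] == imgt, (kab, r["imgt"], imgt)
        if aho is not None:
            assert r["aho"] == aho, (kab, r["aho"], aho)
    # bijectivity per scheme/chain
    for s in SCHEMES:
        for chain in "LH":
            labels = [r[s] for r in rows if r["chain"] == chain]
            assert len(labels) == len(set(labels)), (s, chain)
    out = DATA / "equivalence_v1.tsv"
    with out.open("w") as fh:
        fh.write("# igentropy inter-scheme equivalence table, version v1\n")
        fh.write("# one row per canonical column; approximate outside the "
                 "documented anchor correspondences\n")
        fh.write("\t".join(("chain",) + SCHEMES) + "\n")
        for r in rows:
            fh.write("\t".join([r["chain"]] + [r[s] for s in SCHEMES]) + "\n")
    print(f"wrote {out} ({len(rows)} rows)")


# Approximate Gelfand strand spans and Aho conserved-core spans on the Aho
# grid.  The strand boundaries are not tabulated in the source scheme
# publications at this granularity; these spans are the package's own
# approximation, validated by the invariant that the conserved cysteines
# (Aho 23 and 106, both chains) fall inside annotated strands and core.
STRANDS = {
    "L": [("A", 2, 7), ("A'", 9, 14), ("B", 16, 23), ("C", 43, 49),
          ("C'", 51, 57), ("C''", 75, 80), ("D", 84, 90), ("E", 93, 99),
          ("F", 101, 106), ("G", 139, 146)],
    "H": [("A", 2, 7), ("A''", 9, 14), ("B", 16, 23), ("C", 43, 50),
          ("C'", 52, 56), ("C''", 80, 85), ("D", 88, 94), ("E", 97, 101),
          ("F", 102, 106), ("G", 139, 147)],
}
CORE = {
    "L": [(16, 23), (43, 57), (98, 106)],
    "H": [(16, 23), (43, 56), (97, 106)],
}


def build_annotation():
    out = DATA / "strand_annotation_v1.tsv"
    with out.open("w") as fh:
        fh.write("# igentropy Aho-grid annotation, version v1 (approximate)\n")
        fh.write("chain\tkind\tlabel\taho_start\taho_end\n")
        for chain, spans in STRANDS.items():
            for label, s, e in spans:
                fh.write(f"{chain}\tstrand\t{label}\t{s}\t{e}\n")
        for chain, spans in CORE.items():
            for s, e in spans:
                fh.write(f"{chain}\tcore\tcore\t{s}\t{e}\n")
    print(f"wrote {out}")


# Approximate S. cerevisiae proteome amino-acid frequencies (percent).
# Default neutral reference; users may supply their own 20-row table.
YEAST = {
    "A": 5.5, "C": 1.3, "D": 5.8, "E": 6.5, "F": 4.5, "G": 5.0, "H": 2.2,
    "I": 6.6, "K": 7.3, "L": 9.6, "M": 2.1, "N": 6.1, "P": 4.4, "Q": 3.9,
    "R": 4.4, "S": 9.0, "T": 5.9, "V": 5.6, "W": 1.0, "Y": 3.4,
}


def build_yeast():
    out = DATA / "yeast_reference_v1.tsv"
    with out.open("w") as fh:
        fh.write("# approximate S. cerevisiae proteome amino-acid "
                 "composition (percent); default neutral reference\n")
        fh.write("amino_acid\tweight\n")
        for aa, w in sorted(YEAST.items()):
            fh.write(f"{aa}\t{w}\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    build_equivalence()
    build_annotation()
    build_yeast()
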