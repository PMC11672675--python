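"""CDR1 pivot-point residue distributions.

The pivot point is the structurally conserved CDR1 residue that splits
the loop into two sub-loops (IMGT L29 in kappa, L30 in lambda, H30 in
heavy chains; Kabat L27B/L28/H29 through the equivalence table).  This
script tabulates the residue distribution at each pivot per stratum,
pooling residues under 4% into "other": kappa and lambda pivots should
be dominated by small nonpolar residues (I/V/L), the heavy pivot by Phe,
and the lambda L29 column (kappa-pivot label) by polar Asn/Asp.

Reads results/data/; writes results/pivot/.
"""

from pathlib import Path

import igentropy as ig

IN = Path("results/data")
OUT = Path("results/pivot")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = []
    for chain in ("L", "H"):
        with (IN / f"human_{chain}_kabat.tsv").open() as fh:
            rep = ig.read_numbered_table(fh)
        report = ig.pivot_distribution(rep, cutoff=0.04)
        frames.append(report.to_frame())
        for stratum, dist in report.distributions.items():
            label = report.positions[stratum]
            desc = ", ".join(f"{aa} {f:.0%}" for aa, f in
                             dist.sort_values(ascending=False).items())
            print(f"{stratum} pivot at {label} "
                  f"(n={report.counts[stratum]}): {desc}")
            if stratum in ("kappa", "lambda"):
                ivl = sum(float(dist.get(aa, 0.0)) for aa in "IVL")
                print(f"  combined I+V+L share: {ivl:.0%}")
    import pandas as pd
    pd.concat(frames).to_csv(OUT / "pivot_distributions.tsv", sep="\t",
                             index=False)


if __name__ == "__main__":
    main()
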