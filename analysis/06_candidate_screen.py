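#!/usr/bin/env python
"""Partial-correlation screen of synthetic positional candidates.

Builds expression traits for probes near the mapped locus with three
architectures — a probe-artifact candidate driven only by the local
genotype, a mediating candidate that also carries phenotype-linked
signal, and an unlinked control — then screens them against strain-mean
MPI controlling the peak marker.  Only the mediating candidate should
retain its correlation after control.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lickqtl.expression import ExpressionTrait, candidate_screen
from lickqtl.genome import parse_geno
from lickqtl.scan import scan_single

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis_data"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    geno = parse_geno(DATA / "panel.geno")
    means = pd.read_csv(RESULTS / "strain_means.csv")
    mpi = means[(means["trait"] == "mpi") & (means["stimulus"] == "water")]
    pheno = pd.Series(mpi["mean"].to_numpy(), index=mpi["strain"].to_numpy())

    control = str(scan_single(pheno, geno).peak()["locus"])
    x = geno.dosage(control)
    rng = np.random.default_rng(SEED)
    idx = geno.strains
    z = (pheno[idx] - pheno[idx].mean()) / pheno[idx].std()

    traits = [
        # cis-driven only: strong raw correlation via linkage, no residual
        ExpressionTrait("probe_cis_artifact", "CandA",
                        pd.Series(10.5 + 0.8 * x + rng.normal(0, 0.25, len(x)),
                                  index=idx), "synthetic: cis-only"),
        # cis-driven plus phenotype-linked component (mediator-like)
        ExpressionTrait("probe_mediator", "CandB",
                        pd.Series(12.0 + 0.4 * x - 0.45 * z.to_numpy()
                                  + rng.normal(0, 0.25, len(x)),
                                  index=idx), "synthetic: cis + residual"),
        # unlinked control probe
        ExpressionTrait("probe_unlinked", "CandC",
                        pd.Series(9.0 + rng.normal(0, 0.3, len(x)),
                                  index=idx), "synthetic: noise"),
    ]

    report = candidate_screen(pheno, traits, geno, control)
    report.round(3).to_csv(RESULTS / "candidates.tsv", sep="\t", index=False)
    print(f"screen controlling {control}:")
    print(report[["probe_id", "gene", "n", "r", "partial_r", "partial_p",
                  "cis_marker", "cis_LRS"]].round(3).to_string(index=False))
    print("\nonly the probe with phenotype-linked residual signal keeps a "
          "strong partial correlation after genotype control.")


if __name__ == "__main__":
    main()
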