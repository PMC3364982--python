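#!/usr/bin/env python
"""Extract lick phenotypes (MPI, total licks, VPL) from the raw streams.

Reads the sessions/events CSVs written by 01_simulate_panel.py, computes
per-session inter-lick intervals, applies the 50-160 ms primary window for
MPI and the single-pass +/-3 SD VPL rejection, and writes per-strain
means for mapping.
"""

from pathlib import Path

from lickqtl.licks import build_phenotypes, parse_sessions, strain_means

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "analysis_data"
RESULTS = ROOT / "results"


def main() -> None:
    streams = parse_sessions(DATA / "sessions.csv", DATA / "events.csv")
    pheno = build_phenotypes(streams)
    pheno.to_csv(DATA / "phenotypes.csv", index=False)

    means = strain_means(pheno)
    RESULTS.mkdir(exist_ok=True)
    means.to_csv(RESULTS / "strain_means.csv", index=False)

    water = pheno[pheno["stimulus"] == "water"]
    sucrose = pheno[pheno["stimulus"] == "sucrose"]
    print(f"{len(streams)} sessions -> {pheno['strain'].nunique()} strains")
    print(f"water MPI:   mean {water['mpi'].mean():.2f} ms "
          f"(range {water['mpi'].min():.1f}-{water['mpi'].max():.1f})")
    print(f"sucrose MPI: mean {sucrose['mpi'].mean():.2f} ms")
    n_rej = int(pheno["vpl_rejected"].sum())
    print(f"VPL outliers rejected (+/-3 SD, per stimulus): {n_rej}")
    print(f"undefined MPI sessions: {int(pheno['mpi'].isna().sum())}")
    print(f"strain means -> {RESULTS / 'strain_means.csv'}")


if __name__ == "__main__":
    main()
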