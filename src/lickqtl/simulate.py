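"""Synthetic RI-panel generator: genotypes, phenotypes and lick streams.

Everything downstream (phenotype extraction, heritability, genome scans,
candidate screens) can be exercised end-to-end on panels produced here,
with known planted effects.

Model
-----
* Genotypes: each strain's chromosome is a two-state Markov chain over the
  ordered markers.  The first marker is B or D with probability 1/2; the
  probability that adjacent markers are discordant is the sib-mated RI
  expansion R = 4r/(1+6r) of the Haldane recombination fraction r for the
  cM gap.  Chromosomes are independent; only B and D are emitted.
* Strain phenotype (MPI, ms): baseline + sum_j effect_j * x_j + polygenic
  N(0, sigma2_strain), with x_j = +1 for D/D and -1 for B/B at each planted
  locus; animal values add N(0, sigma2_env).
* Lick streams: bursts of licks whose within-burst ILIs are
  Normal(true MPI, within_burst_sd) truncated to the 50-160 ms primary
  window; a fraction of ILIs (and every between-burst gap) is replaced by a
  shifted-exponential pause strictly longer than 160 ms, so pauses always
  fall outside the primary window.

The ``paper_matched`` preset encodes the study conditions this package is
calibrated to: 64 strains x 6 mice, baseline MPI 110 ms, total genetic
variance 32.6 ms^2 of which one planted major locus with a per-allele
effect of 4.35 ms contributes 4.35^2 = 18.9 ms^2, and within-strain
environmental variance 10 ms^2 — giving broad-sense h^2 = 32.6/(32.6+20)
= 0.62 and a D/D vs B/B haplotype-group difference of ~9 ms at the
planted locus.

One master seed drives everything; per-stage substreams are spawned at
fixed offsets so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenoMap, GenotypeMatrix, ri_transition_probability, uniform_map
from .licks import LickEventStream
from .quantgen import StrainPhenotypeTable

PRIMARY_LO, PRIMARY_HI = 50.0, 160.0

# fixed substream offsets off the master seed (stage independence)
_STAGE_GENO, _STAGE_PHENO, _STAGE_LICKS, _STAGE_AUX = 0, 1, 2, 3


def _rng(seed: int, stage: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage), int(extra)])


@dataclass(frozen=True)
class QTLSpec:
    """A planted additive locus.

    ``per_allele_effect`` is in trait units (ms) per substitution of the D
    allele: strain mean shifts by +effect for D/D and -effect for B/B.
    Dominance is structurally zero in an RI panel (no heterozygotes).
    """

    marker_name: str
    per_allele_effect: float
    dominance: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic panel in one place (see module docstring)."""

    n_strains: int = 64
    mice_per_strain: int = 6
    baseline_mpi: float = 110.0  # ms
    sigma2_strain: float = 13.6775  # ms^2, polygenic (excl. planted QTLs)
    sigma2_env: float = 10.0  # ms^2, within-strain
    qtls: tuple[QTLSpec, ...] = ()
    burst_count: int = 20
    licks_per_burst: int = 30
    within_burst_sd: float = 8.0  # ms
    pause_probability: float = 0.02
    pause_mean: float = 1500.0  # ms, must exceed the primary window
    sucrose_shift: float = 0.66  # ms added to MPI under sucrose
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_strain < 0 or self.sigma2_env < 0:
            raise ValueError("variances must be non-negative")
        if self.pause_mean <= PRIMARY_HI:
            raise ValueError("pause_mean must exceed the 160 ms primary bound")
        if not 0 <= self.pause_probability <= 1:
            raise ValueError("pause_probability must be a fraction")


#: marker carrying the planted major-effect locus in the packaged preset
PAPER_MATCHED_MARKER = "c01m07"

#: total between-strain genetic variance of the preset (polygenic + QTL)
PAPER_MATCHED_VA = 32.6  # ms^2
PAPER_MATCHED_EFFECT = 4.35  # ms per D allele (D lowers MPI)


def paper_matched(seed: int = 0) -> tuple[GenoMap, GeneratorConfig]:
    """The packaged study-condition preset: map + generator configuration.

    64 strains x 6 mice; one planted locus mid-chromosome-1 whose D allele
    lowers MPI by 4.35 ms; residual polygenic variance chosen so the total
    genetic variance is 32.6 ms^2 and h^2 = 0.62 with sigma2_env = 10 ms^2.
    """
    gmap = uniform_map(n_chrom=19, markers_per_chrom=15, spacing_cM=5.0)
    cfg = GeneratorConfig(
        n_strains=64,
        mice_per_strain=6,
        baseline_mpi=110.0,
        sigma2_strain=PAPER_MATCHED_VA - PAPER_MATCHED_EFFECT**2,
        sigma2_env=10.0,
        qtls=(QTLSpec(PAPER_MATCHED_MARKER, -PAPER_MATCHED_EFFECT),),
        seed=seed,
    )
    return gmap, cfg


def simulate_ri_genotypes(
    gmap: GenoMap, n_strains: int, seed: int
) -> GenotypeMatrix:
    """Simulate fully inbred RI genotypes as per-chromosome Markov chains.

    First marker of each chromosome is B or D with probability 1/2; the
    flip probability between adjacent markers is R = 4r/(1+6r) with r the
    Haldane recombination fraction for the cM gap.  Only B/D are emitted.
    """
    if n_strains <= 0:
        raise ValueError("n_strains must be positive")
    if len(gmap) < 1:
        raise ValueError("map must contain at least one marker")
    rng = _rng(seed, _STAGE_GENO)
    t = gmap.table
    n_markers = len(t)
    # per-interval flip probability; crossing a chromosome boundary -> 0.5
    cm = t["cM"].to_numpy(dtype=float)
    chrom = t["chrom"].to_numpy()
    flip_p = np.empty(n_markers)
    flip_p[0] = 0.5
    same_chrom = chrom[1:] == chrom[:-1]
    gaps = np.where(same_chrom, cm[1:] - cm[:-1], 0.0)
    flip_p[1:] = np.where(same_chrom, ri_transition_probability(gaps), 0.5)
    # cumulative XOR of flip events gives the chain; first "flip" at p=0.5
    # doubles as the independent chromosome start
    flips = rng.random((n_strains, n_markers)) < flip_p[None, :]
    state = np.cumsum(flips, axis=1) % 2  # 0/1 alternating with each flip
    codes = np.where(state == 0, "B", "D")
    strains = [f"RIX{i + 1:03d}" for i in range(n_strains)]
    return GenotypeMatrix(strains=strains, gmap=gmap, codes=codes)


def simulate_strain_phenotypes(
    geno: GenotypeMatrix, cfg: GeneratorConfig
) -> StrainPhenotypeTable:
    """Animal-level MPI values with planted QTLs and two variance tiers.

    Strain mean = baseline + sum_j effect_j * x_j + N(0, sigma2_strain);
    each animal adds N(0, sigma2_env).  The returned table carries the
    noiseless per-strain genetic values in ``.data.attrs['true_strain_means']``.
    """
    rng = _rng(cfg.seed, _STAGE_PHENO)
    n = geno.n_strains
    genetic = np.full(n, cfg.baseline_mpi)
    for q in cfg.qtls:
        x = geno.dosage(q.marker_name)  # KeyError for unknown marker
        genetic = genetic + q.per_allele_effect * np.nan_to_num(x)
    true_means = genetic + rng.normal(0.0, np.sqrt(cfg.sigma2_strain), size=n)
    rows = []
    for i, strain in enumerate(geno.strains):
        animal_vals = true_means[i] + rng.normal(
            0.0, np.sqrt(cfg.sigma2_env), size=cfg.mice_per_strain
        )
        for a, val in enumerate(animal_vals):
            rows.append({"animal": f"{strain}_a{a + 1}", "strain": strain,
                         "stimulus": "water", "day": 2, "mpi": val})
    df = pd.DataFrame(rows)
    df.attrs["true_strain_means"] = pd.Series(true_means, index=geno.strains)
    return StrainPhenotypeTable(df)


def simulate_lick_session(
    true_mpi: float, cfg: GeneratorConfig, seed: int
) -> LickEventStream:
    """One session: ``burst_count`` bursts of ``licks_per_burst`` licks.

    Within-burst ILIs ~ Normal(true_mpi, within_burst_sd) truncated to the
    primary window; each within-burst ILI is independently replaced by a
    pause with probability ``pause_probability``, and bursts are separated
    by a pause.  Pauses are 160 ms + Exponential(pause_mean - 160), hence
    strictly outside the primary window.  Timestamps are integer ms,
    strictly increasing.
    """
    if not (PRIMARY_LO < true_mpi < PRIMARY_HI):
        raise ValueError(f"true_mpi {true_mpi} outside ({PRIMARY_LO}, {PRIMARY_HI})")
    rng = _rng(seed, _STAGE_LICKS)
    ilis: list[float] = []
    for b in range(cfg.burst_count):
        if b > 0:
            ilis.append(_draw_pause(rng, cfg))
        for _ in range(cfg.licks_per_burst - 1):
            if cfg.pause_probability > 0 and rng.random() < cfg.pause_probability:
                ilis.append(_draw_pause(rng, cfg))
            else:
                ilis.append(_draw_primary(rng, true_mpi, cfg.within_burst_sd))
    t = np.empty(len(ilis) + 1, dtype=np.int64)
    t[0] = 0
    t[1:] = np.round(np.cumsum(ilis)).astype(np.int64)
    t = np.maximum.accumulate(t)  # guard against rounding collisions
    t[1:] += np.cumsum(np.diff(t) == 0)  # enforce strict increase
    return LickEventStream(session_id=f"sim{seed}", timestamps=t)


def _draw_primary(rng: np.random.Generator, mu: float, sd: float) -> float:
    if sd == 0:
        return mu
    while True:  # truncation to the primary window; acceptance is ~1 in practice
        v = rng.normal(mu, sd)
        if PRIMARY_LO <= v <= PRIMARY_HI:
            return v


def _draw_pause(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    return PRIMARY_HI + 1.0 + rng.exponential(cfg.pause_mean - PRIMARY_HI)


def simulate_null_panel(
    gmap: GenoMap, n_strains: int, seed: int, sigma: float = 1.0
) -> tuple[GenotypeMatrix, pd.Series]:
    """Genotypes plus an iid-normal strain phenotype with no genetic signal.

    Used for calibrating permutation thresholds: under this null the
    observed genome-wide max LRS is exchangeable with permuted ones.
    """
    geno = simulate_ri_genotypes(gmap, n_strains, seed)
    rng = _rng(seed, _STAGE_AUX)
    pheno = pd.Series(rng.normal(0.0, sigma, size=n_strains), index=geno.strains)
    return geno, pheno


def simulate_panel(
    cfg: GeneratorConfig, gmap: GenoMap | None = None
) -> tuple[GenotypeMatrix, StrainPhenotypeTable, pd.DataFrame, pd.DataFrame]:
    """Full synthetic experiment: genotypes, phenotypes and lick sessions.

    Each animal is tested on day 2 (water) and day 3 (sucrose); sucrose
    shifts the true MPI by ``cfg.sucrose_shift`` ms.  Returns
    (genotypes, phenotype table, sessions frame, events frame) where the
    two frames follow the sessions.csv / events.csv layout.
    """
    if gmap is None:
        gmap = uniform_map()
    geno = simulate_ri_genotypes(gmap, cfg.n_strains, cfg.seed)
    pheno = simulate_strain_phenotypes(geno, cfg)
    aux = _rng(cfg.seed, _STAGE_AUX, 1)
    sessions, events = [], []
    sid = 0
    for _, row in pheno.data.iterrows():
        animal, strain = row["animal"], row["strain"]
        weight = float(np.round(aux.normal(25.0, 2.0), 1))
        vpl_true = max(0.4, aux.normal(1.0, 0.1))  # uL/lick
        for day, stimulus in ((2, "water"), (3, "sucrose")):
            sid += 1
            mu = float(np.clip(
                row["mpi"] + (cfg.sucrose_shift if stimulus == "sucrose" else 0.0),
                PRIMARY_LO + 1, PRIMARY_HI - 1))
            stream = simulate_lick_session(mu, cfg, seed=int(aux.integers(2**31)))
            n_licks = stream.n_licks
            volume = np.round(n_licks * vpl_true / 1000.0, 3)
            session_id = f"s{sid:05d}"
            sessions.append({
                "session_id": session_id, "animal_id": animal, "strain": strain,
                "sex": "F" if aux.random() < 0.5 else "M", "day": day,
                "stimulus": stimulus, "body_weight_g": weight,
                "volume_ml": volume,
            })
            events.append(pd.DataFrame(
                {"session_id": session_id, "t_ms": stream.timestamps}))
    sessions_df = pd.DataFrame(sessions)
    events_df = pd.concat(events, ignore_index=True)
    return geno, pheno, sessions_df, events_df


def with_seed(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``cfg`` with a different master seed."""
    return replace(cfg, seed=seed)
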