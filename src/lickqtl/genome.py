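"""Genetic maps and genotype matrices for recombinant inbred (RI) panels.

A BXD-style RI panel descends from a cross of two inbred progenitors
(B = C57BL/6J, D = DBA/2J) followed by repeated sib-mating, so every strain
is homozygous B/B or D/D at almost every locus.  Genotypes are stored as
single-character codes ``B``/``D`` with ``H`` (residual heterozygosity) and
``U`` (unknown) treated as missing in the numeric view used for mapping.

The text format read and written here is the GeneNetwork ``.geno`` dialect:
``#`` comment lines, ``@name:value`` metadata lines, then a tab-separated
table with columns ``Chr  Locus  cM  Mb`` followed by one column per strain.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_CODES = frozenset("BDHU")

#: numeric dosage per code: B/B = -1, D/D = +1, H and U missing
CODE_TO_DOSAGE = {"B": -1.0, "D": 1.0, "H": np.nan, "U": np.nan}


def haldane_recombination(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Single-meiosis recombination fraction r for a map distance in cM.

    Haldane's map function (no interference): r = (1 - exp(-2d/100)) / 2.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def ri_transition_probability(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Probability that adjacent markers have discordant genotypes in a
    sib-mated RI strain.

    Repeated sib-mating expands the effective map: for single-meiosis
    recombination fraction r (Haldane, from the cM distance), the RI-strain
    discordance probability is R = 4r / (1 + 6r) (Haldane-Waddington).
    """
    r = np.asarray(haldane_recombination(d_cM), dtype=float)
    R = 4.0 * r / (1.0 + 6.0 * r)
    return R if R.ndim else float(R)


@dataclass(frozen=True)
class GenoMap:
    """Ordered marker map: name, chromosome, genetic (cM) and physical (Mb)
    position per marker.

    Markers must be grouped by chromosome with non-decreasing positions
    within each chromosome, and names must be unique.
    """

    table: pd.DataFrame  # columns: name, chrom, cM, Mb

    REQUIRED = ("name", "chrom", "cM", "Mb")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"map table missing columns: {missing}")
        if t["name"].duplicated().any():
            dup = t.loc[t["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate marker name: {dup!r}")
        for chrom, grp in t.groupby("chrom", sort=False):
            if not grp["cM"].is_monotonic_increasing:
                raise ValueError(f"cM positions decrease on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    @property
    def chromosomes(self) -> list:
        seen = []
        for c in self.table["chrom"]:
            if c not in seen:
                seen.append(c)
        return seen

    def index_of(self, marker: str) -> int:
        idx = np.flatnonzero(self.table["name"].to_numpy() == marker)
        if idx.size == 0:
            raise KeyError(f"unknown marker {marker!r}")
        return int(idx[0])


def uniform_map(
    n_chrom: int = 19,
    markers_per_chrom: int = 15,
    spacing_cM: float = 5.0,
    mb_per_cM: float = 2.0,
) -> GenoMap:
    """Evenly spaced synthetic marker map over ``n_chrom`` autosomes.

    Marker names follow ``c{chrom:02d}m{index:02d}``; physical positions are
    a fixed Mb-per-cM scaling, adequate for simulation and interval reporting.
    """
    rows = []
    for c in range(1, n_chrom + 1):
        for m in range(markers_per_chrom):
            cm = m * spacing_cM
            rows.append((f"c{c:02d}m{m:02d}", str(c), cm, cm * mb_per_cM))
    return GenoMap(pd.DataFrame(rows, columns=["name", "chrom", "cM", "Mb"]))


@dataclass
class GenotypeMatrix:
    """Strain x marker genotype codes plus the marker map.

    ``codes`` is a (n_strains, n_markers) array of single characters in
    {B, D, H, U}; the ``dosage`` view maps B/B to -1, D/D to +1 and H/U to
    NaN, the coding used by all mapping routines (so a positive additive
    effect means the D allele raises the trait).
    """

    strains: list[str]
    gmap: GenoMap
    codes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.shape != (len(self.strains), len(self.gmap)):
            raise ValueError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.strains)} strains, {len(self.gmap)} markers)"
            )
        bad = set(np.unique(self.codes)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def marker_names(self) -> list[str]:
        return self.gmap.names

    def dosage(self, marker: str | None = None) -> np.ndarray:
        """Numeric genotypes (-1 / +1 / NaN); one column or the full matrix."""
        num = np.full(self.codes.shape, np.nan)
        for code, val in CODE_TO_DOSAGE.items():
            num[self.codes == code] = val
        if marker is None:
            return num
        return num[:, self.gmap.index_of(marker)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.strains, columns=self.gmap.names)


def parse_geno(path: str | Path | io.TextIOBase) -> GenotypeMatrix:
    """Read a GeneNetwork-style ``.geno`` file.

    ``#`` lines are comments, ``@key:value`` lines are recorded as metadata.
    The header row must be ``Chr Locus cM Mb <strain...>`` (tab-separated).
    H and U cells are kept as codes and become NaN in the dosage view.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        origin = "<stream>"
    else:
        origin = str(path)
        lines = Path(path).read_text().splitlines()

    metadata: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("@"):
            key, _, val = line[1:].partition(":")
            metadata[key.strip()] = val.strip()
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header[:4] != ["Chr", "Locus", "cM", "Mb"]:
                raise ValueError(
                    f"{origin}:{lineno}: expected header starting "
                    f"'Chr\\tLocus\\tcM\\tMb', got {header[:4]}"
                )
            if len(header) < 5:
                raise ValueError(f"{origin}:{lineno}: no strain columns in header")
            continue
        if len(fields) != len(header):
            raise ValueError(
                f"{origin}:{lineno}: row has {len(fields)} fields, "
                f"header has {len(header)}"
            )
        rows.append(fields)

    if header is None or not rows:
        raise ValueError(f"{origin}: no genotype rows found")

    strains = header[4:]
    map_rows, code_cols = [], []
    for i, fields in enumerate(rows):
        chrom, locus, cm, mb = fields[:4]
        map_rows.append((locus, chrom, float(cm), float(mb)))
        codes = fields[4:]
        for j, c in enumerate(codes):
            if c not in VALID_CODES:
                raise ValueError(
                    f"{origin}: invalid code {c!r} at marker {locus!r}, "
                    f"strain {strains[j]!r}"
                )
        code_cols.append(codes)

    gmap = GenoMap(pd.DataFrame(map_rows, columns=["name", "chrom", "cM", "Mb"]))
    codes = np.asarray(code_cols, dtype="<U1").T  # strains x markers
    return GenotypeMatrix(strains=list(strains), gmap=gmap, codes=codes, metadata=metadata)


def write_geno(geno: GenotypeMatrix, path: str | Path, name: str = "synthetic") -> None:
    """Write a GenotypeMatrix in the ``.geno`` dialect read by :func:`parse_geno`."""
    lines = [f"@name:{name}", "@type:riset", "@mat:B", "@pat:D", "@het:H", "@unk:U"]
    lines.append("\t".join(["Chr", "Locus", "cM", "Mb", *geno.strains]))
    t = geno.gmap.table
    for j in range(len(t)):
        row = t.iloc[j]
        cells = geno.codes[:, j].tolist()
        lines.append(
            "\t".join([str(row["chrom"]), row["name"], f"{row['cM']:g}",
                       f"{row['Mb']:g}", *cells])
        )
    Path(path).write_text("\n".join(lines) + "\n")
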