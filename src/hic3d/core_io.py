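"""Domain types and file I/O for binned Hi-C analysis.

Coordinates are 0-based half-open throughout.  Contact matrices are stored
as sparse upper-triangle triplets over a genome-wide bin index; loops,
intervals, signal tracks, methylation tables and expression matrices use
the plain-text formats common in the field (BEDPE, BED, bedGraph, TSV,
HiC-Pro triplet matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an object violates a domain invariant."""


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


# ---------------------------------------------------------------------------
# Assembly / bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("names and lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        if any(l < 1 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be >= 1")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeAssembly":
        return cls(tuple(sizes), tuple(int(v) for v in sizes.values()))

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeAssembly":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(tuple(df["chrom"].astype(str)), tuple(df["length"].astype(int)))

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class BinTable:
    """Fixed-resolution tiling of an assembly with a global bin index.

    Bins tile each chromosome without gaps; the last bin of a chromosome may
    be shorter than the resolution.  Global indices are contiguous from 0 in
    chromosome order.
    """

    def __init__(self, assembly: GenomeAssembly, resolution: int):
        if resolution < 1:
            raise ValidationError("resolution must be >= 1")
        self.assembly = assembly
        self.resolution = int(resolution)
        self._n_per_chrom = np.array(
            [-(-l // resolution) for l in assembly.chrom_lengths], dtype=np.int64
        )
        self._offsets = np.concatenate([[0], np.cumsum(self._n_per_chrom)])

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    def n_bins_chrom(self, chrom: str) -> int:
        return int(self._n_per_chrom[self.assembly.chrom_names.index(chrom)])

    def chrom_offset(self, chrom: str) -> int:
        return int(self._offsets[self.assembly.chrom_names.index(chrom)])

    def chrom_slice(self, chrom: str) -> slice:
        i = self.assembly.chrom_names.index(chrom)
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` on ``chrom``."""
        if not (0 <= pos < self.assembly.length(chrom)):
            raise ValidationError(f"position {pos} outside {chrom}")
        return self.chrom_offset(chrom) + pos // self.resolution

    def chrom_of_bin(self, idx: int) -> str:
        if not (0 <= idx < self.n_bins):
            raise ValidationError(f"bin index {idx} out of range")
        ci = int(np.searchsorted(self._offsets, idx, side="right")) - 1
        return self.assembly.chrom_names[ci]

    def location(self, idx: int) -> GenomicInterval:
        if not (0 <= idx < self.n_bins):
            raise ValidationError(f"bin index {idx} out of range")
        ci = int(np.searchsorted(self._offsets, idx, side="right")) - 1
        chrom = self.assembly.chrom_names[ci]
        local = idx - int(self._offsets[ci])
        start = local * self.resolution
        end = min(start + self.resolution, self.assembly.chrom_lengths[ci])
        return GenomicInterval(chrom, start, end)

    def chrom_index_of_bins(self, idx: np.ndarray) -> np.ndarray:
        return np.searchsorted(self._offsets, idx, side="right") - 1

    def to_dataframe(self) -> pd.DataFrame:
        rows = [self.location(i) for i in range(self.n_bins)]
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in rows],
                "start": [r.start for r in rows],
                "end": [r.end for r in rows],
                "index": np.arange(self.n_bins),
            }
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinTable)
            and self.assembly == other.assembly
            and self.resolution == other.resolution
        )

    def __hash__(self):  # pragma: no cover - identity hashing is fine
        return hash((self.assembly, self.resolution))


# ---------------------------------------------------------------------------
# Contact matrix
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Sparse upper-triangle contact counts over a BinTable.

    Triplets with i > j are folded into the upper triangle on construction
    (summing if both orientations are present).  Counts are floats so that
    balanced matrices reuse the same container.
    """

    bin_table: BinTable
    row: np.ndarray
    col: np.ndarray
    count: np.ndarray
    balanced: bool = False
    biases: np.ndarray | None = None

    def __post_init__(self) -> None:
        row = np.asarray(self.row, dtype=np.int64)
        col = np.asarray(self.col, dtype=np.int64)
        count = np.asarray(self.count, dtype=np.float64)
        if not (row.shape == col.shape == count.shape):
            raise ValidationError("triplet arrays differ in length")
        n = self.bin_table.n_bins
        if row.size and (
            row.min() < 0 or col.min() < 0 or row.max() >= n or col.max() >= n
        ):
            raise ValidationError("bin index out of range")
        if count.size and count.min() < 0:
            raise ValidationError("negative contact count")
        # fold into upper triangle and merge duplicates
        swap = row > col
        row2 = np.where(swap, col, row)
        col2 = np.where(swap, row, col)
        key = row2 * n + col2
        uniq, inv = np.unique(key, return_inverse=True)
        merged = np.bincount(inv, weights=count, minlength=uniq.size)
        self.row = (uniq // n).astype(np.int64)
        self.col = (uniq % n).astype(np.int64)
        self.count = merged.astype(np.float64)
        if self.balanced and self.biases is None:
            raise ValidationError("balanced matrix requires biases")

    @property
    def total_valid_pairs(self) -> float:
        return float(self.count.sum())

    @property
    def n_entries(self) -> int:
        return int(self.row.size)

    def cis_mask(self) -> np.ndarray:
        bt = self.bin_table
        return bt.chrom_index_of_bins(self.row) == bt.chrom_index_of_bins(self.col)

    def cis_dense(self, chrom: str) -> np.ndarray:
        """Symmetric dense cis sub-matrix for one chromosome."""
        sl = self.bin_table.chrom_slice(chrom)
        n = sl.stop - sl.start
        m = np.zeros((n, n))
        sel = (
            (self.row >= sl.start)
            & (self.row < sl.stop)
            & (self.col >= sl.start)
            & (self.col < sl.stop)
        )
        r = self.row[sel] - sl.start
        c = self.col[sel] - sl.start
        m[r, c] = self.count[sel]
        m[c, r] = self.count[sel]
        return m

    def trans_block(self, chrom_a: str, chrom_b: str) -> np.ndarray:
        """Dense chrom_a x chrom_b block (rows = chrom_a bins)."""
        sa = self.bin_table.chrom_slice(chrom_a)
        sb = self.bin_table.chrom_slice(chrom_b)
        m = np.zeros((sa.stop - sa.start, sb.stop - sb.start))
        for r0, c0 in ((sa, sb), (sb, sa)):
            sel = (
                (self.row >= r0.start)
                & (self.row < r0.stop)
                & (self.col >= c0.start)
                & (self.col < c0.stop)
            )
            if r0 is sa:
                m[self.row[sel] - sa.start, self.col[sel] - sb.start] += self.count[sel]
            else:
                m[self.col[sel] - sa.start, self.row[sel] - sb.start] += self.count[sel]
        return m

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bin_table,
            self.row.copy(),
            self.col.copy(),
            self.count.copy(),
            balanced=self.balanced,
            biases=None if self.biases is None else self.biases.copy(),
        )


# ---------------------------------------------------------------------------
# Loops / TADs / SVs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Loop:
    """Significant focal contact between two bin-aligned anchors."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    observed: float
    expected_p: float
    p_value: float
    q_value: float
    sample_id: str = "."

    def __post_init__(self) -> None:
        if self.anchor1.chrom == self.anchor2.chrom and (
            self.anchor1.start,
            self.anchor1.end,
        ) > (self.anchor2.start, self.anchor2.end):
            raise ValidationError("cis loop anchors must be coordinate-ordered")
        for v in (self.p_value, self.q_value):
            if not (0.0 <= v <= 1.0):
                raise ValidationError("p/q values must lie in [0, 1]")

    def anchor_key(self) -> tuple:
        a1, a2 = self.anchor1, self.anchor2
        return (a1.chrom, a1.start, a1.end, a2.chrom, a2.start, a2.end)


@dataclass(frozen=True)
class TAD:
    """Topologically associating domain with per-flank boundary p-values."""

    interval: GenomicInterval
    boundary_p: tuple[float, float] = (float("nan"), float("nan"))
    neo: bool = False


@dataclass(frozen=True)
class StructuralVariant:
    """Typed breakpoint pair with the somatic allele fraction carrying it."""

    sv_type: str  # tandem_duplication | deletion | inversion | translocation
    bp_a: tuple[str, int]
    bp_b: tuple[str, int]
    orientation: tuple[str, str] = ("+", "+")
    allele_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.sv_type not in (
            "tandem_duplication",
            "deletion",
            "inversion",
            "translocation",
        ):
            raise ValidationError(f"unknown SV type {self.sv_type!r}")
        if not (0.0 < self.allele_fraction <= 1.0):
            raise ValidationError("allele_fraction must be in (0, 1]")
        if self.sv_type != "translocation":
            if self.bp_a[0] != self.bp_b[0]:
                raise ValidationError("cis SV breakpoints must share a chromosome")
            if not self.bp_a[1] < self.bp_b[1]:
                raise ValidationError("cis SV breakpoints must be ordered")


# ---------------------------------------------------------------------------
# Tracks / methylation / expression / genes
# ---------------------------------------------------------------------------

@dataclass
class SignalTrack:
    """Sorted, non-overlapping intervals with one value each (bedGraph)."""

    data: pd.DataFrame  # columns chrom, start, end, value
    sample_id: str = "."

    def __post_init__(self) -> None:
        req = ["chrom", "start", "end", "value"]
        if list(self.data.columns[:4]) != req:
            self.data = self.data.rename(
                columns=dict(zip(self.data.columns[:4], req))
            )
        self.data = self.data.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in self.data.groupby("chrom", sort=False):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValidationError(f"overlapping intervals on {chrom}")
            if (grp["start"].values >= grp["end"].values).any():
                raise ValidationError(f"empty interval on {chrom}")


@dataclass
class MethylationProfile:
    """Per-CpG methylation fractions for one sample."""

    data: pd.DataFrame  # columns chrom, pos, beta, coverage
    sample_id: str = "."
    group: str = "."

    def __post_init__(self) -> None:
        d = self.data
        if ((d["beta"] < 0) | (d["beta"] > 1)).any():
            raise ValidationError("beta outside [0, 1]")
        if (d["coverage"] < 0).any():
            raise ValidationError("negative coverage")
        self.data = d.sort_values(["chrom", "pos"]).reset_index(drop=True)


@dataclass
class ExpressionMatrix:
    """Genes x samples normalized expression with per-sample group labels."""

    values: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if (self.values.values < 0).any():
            raise ValidationError("negative expression values")
        missing = set(self.values.columns) - set(self.sample_groups.index)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)}")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if not (self.body.start <= self.tss < self.body.end):
            raise ValidationError(f"TSS outside gene body for {self.gene_id}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bins_bed(path: str | Path) -> BinTable:
    """Read a HiC-Pro style bin file (chrom, start, end, index).

    The index column may be 0- or 1-based; the offset is auto-detected from
    the first bin.
    """
    df = _read_table(path, ["chrom", "start", "end", "index"])
    first = int(df["index"].iloc[0])
    if first not in (0, 1):
        raise ParseError(f"cannot autodetect index origin (first index {first})")
    df["index"] = df["index"].astype(int) - first
    df = df.sort_values("index").reset_index(drop=True)
    if not (df["index"].values == np.arange(len(df))).all():
        raise ValidationError("bin indices are not contiguous from 0")
    widths = (df["end"] - df["start"]).values
    resolution = int(np.bincount(widths.astype(int)).argmax()) if len(df) else 0
    sizes: dict[str, int] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].values
        ends = grp["end"].values
        if starts[0] != 0 or (starts[1:] != ends[:-1]).any():
            raise ValidationError(f"bins do not tile {chrom} without gaps")
        if (widths[grp.index[:-1]] != resolution).any():
            raise ValidationError(f"non-uniform bin width on {chrom}")
        sizes[str(chrom)] = int(ends[-1])
    return BinTable(GenomeAssembly.from_dict(sizes), resolution)


def read_contact_matrix(
    matrix_path: str | Path, bins_path: str | Path
) -> ContactMatrix:
    """Read a HiC-Pro triplet matrix (``i j count``) with its bin file.

    Lower-triangle entries are folded into the upper triangle; the matrix
    index origin follows the bin file's autodetected origin.
    """
    bt = read_bins_bed(bins_path)
    # re-detect origin: the bin file read normalizes to 0-based, but the
    # matrix file shares the bin file's original origin
    with open(bins_path) as fh:
        first_index = int(fh.readline().split()[3])
    rows, cols, counts = [], [], []
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{matrix_path}:{lineno}: expected 3 fields")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise ParseError(
                    f"{matrix_path}:{lineno}: non-numeric field"
                ) from None
            rows.append(i - first_index)
            cols.append(j - first_index)
            counts.append(c)
    row = np.asarray(rows, dtype=np.int64)
    col = np.asarray(cols, dtype=np.int64)
    if row.size and (
        row.min() < 0 or col.min() < 0 or row.max() >= bt.n_bins or col.max() >= bt.n_bins
    ):
        raise ValidationError("matrix references bin index outside bin file")
    return ContactMatrix(bt, row, col, np.asarray(counts))


def write_contact_matrix(
    cm: ContactMatrix, matrix_path: str | Path, bins_path: str | Path
) -> None:
    cm.bin_table.to_dataframe().to_csv(bins_path, sep="\t", header=False, index=False)
    order = np.lexsort((cm.col, cm.row))
    with open(matrix_path, "w") as fh:
        for i, j, c in zip(cm.row[order], cm.col[order], cm.count[order]):
            fh.write(f"{i}\t{j}\t{c:g}\n")


_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "observed", "expected_p", "p_value", "q_value", "sample_id",
]


def write_loops_bedpe(loops: Sequence[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_BEDPE_COLS) + "\n")
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        a1.chrom, a1.start, a1.end, a2.chrom, a2.start, a2.end,
                        ".", 0, ".", ".",
                        repr(lp.observed), repr(lp.expected_p),
                        repr(lp.p_value), repr(lp.q_value), lp.sample_id,
                    )
                )
                + "\n"
            )


def read_loops_bedpe(path: str | Path) -> list[Loop]:
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(_BEDPE_COLS):
                raise ParseError(f"{path}:{lineno}: expected {len(_BEDPE_COLS)} fields")
            try:
                loops.append(
                    Loop(
                        GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                        GenomicInterval(parts[3], int(parts[4]), int(parts[5])),
                        observed=float(parts[10]),
                        expected_p=float(parts[11]),
                        p_value=float(parts[12]),
                        q_value=float(parts[13]),
                        sample_id=parts[14],
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return loops


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_signal_track(path: str | Path, sample_id: str = ".") -> SignalTrack:
    df = _read_table(path, ["chrom", "start", "end", "value"])
    return SignalTrack(df, sample_id=sample_id)


def write_signal_track(track: SignalTrack, path: str | Path) -> None:
    track.data.to_csv(path, sep="\t", header=False, index=False)


def read_methylation(
    path: str | Path, sample_id: str = ".", group: str = "."
) -> MethylationProfile:
    df = pd.read_csv(path, sep="\t")
    req = {"chrom", "pos", "beta", "coverage"}
    if not req.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(req - set(df.columns))}")
    return MethylationProfile(df[list(["chrom", "pos", "beta", "coverage"])],
                              sample_id=sample_id, group=group)


def read_expression(
    path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    groups = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample", "group"]
    ).set_index("sample")["group"]
    return ExpressionMatrix(values, groups)


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    req = {"gene_id", "chrom", "tss", "strand", "start", "end"}
    if not req.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(req - set(df.columns))}")
    return [
        GeneAnnotation(
            str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand),
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
        )
        for r in df.itertuples()
    ]


def _read_table(path: str | Path, names: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#", names=names,
            usecols=range(len(names)),
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    return df


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def qc_filter_samples(
    samples: Mapping[str, ContactMatrix], min_valid_pairs: float = 1e8
) -> tuple[dict[str, ContactMatrix], dict[str, ContactMatrix]]:
    """Partition samples by total valid pairs.

    Samples below the threshold are excluded from loop-level analysis but
    are returned (not discarded) because large structural variants remain
    detectable at low depth.
    """
    kept = {s: m for s, m in samples.items() if m.total_valid_pairs >= min_valid_pairs}
    excluded = {s: m for s, m in samples.items() if s not in kept}
    return kept, excluded
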