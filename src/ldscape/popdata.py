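"""Core data model and I/O for phased genotypes, marker maps and result tables.

The substrate for every analysis stage is a :class:`HaplotypeSet`: a matrix of
0/1 alleles with two rows (gametes) per individual, columns ordered by the
accompanying :class:`MarkerMap`.  Allele code ``1`` always refers to
``allele1`` of the map (the ALT allele when reading VCF), and the same map is
shared across populations so that the *sign* of the LD correlation r is
comparable between them — comparing linkage phase across breeds is meaningless
without a shared allele coding.

Missing phased alleles are not supported downstream; inputs must be imputed
and phased upstream.  Unphased genotypes (with missingness) exist only in
:class:`GenotypeSet`, which is consumed by the QC stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MAP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele1", "allele2"]

#: chromosome labels treated as autosomes by default (cattle: BTA1..BTA29)
DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 30))


def _chrom_sort_key(labels: pd.Series) -> pd.Series:
    """Numeric-aware ordering key for chromosome labels ('2' < '10' < 'X')."""
    num = pd.to_numeric(labels, errors="coerce")
    # non-numeric labels sort after all numeric ones, lexicographically
    return pd.Series(
        list(zip(num.isna(), num.fillna(0.0), labels.astype(str))),
        index=labels.index,
    )


class MarkerMap:
    """Per-SNP chromosome, 1-based physical position and allele labels.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``snp_id, chrom, pos_bp, allele1, allele2``.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        out = df.loc[:, MAP_COLUMNS].copy()
        out["snp_id"] = out["snp_id"].astype(str)
        out["chrom"] = out["chrom"].astype(str)
        out["pos_bp"] = out["pos_bp"].astype(np.int64)
        out["allele1"] = out["allele1"].astype(str)
        out["allele2"] = out["allele2"].astype(str)
        if (out["pos_bp"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if (out["allele1"] == out["allele2"]).any():
            bad = out.loc[out["allele1"] == out["allele2"], "snp_id"].iloc[0]
            raise ValueError(f"marker {bad!r} has identical allele labels")
        self.df = out.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    def sort_order(self) -> np.ndarray:
        """Stable ordering by (chromosome, position)."""
        key = _chrom_sort_key(self.df["chrom"])
        tmp = pd.DataFrame({"k": key, "p": self.df["pos_bp"]})
        return tmp.sort_values(["k", "p"], kind="stable").index.to_numpy()

    def is_sorted(self) -> bool:
        order = self.sort_order()
        return bool(np.array_equal(order, np.arange(self.n_markers)))

    def subset(self, idx) -> "MarkerMap":
        return MarkerMap(self.df.iloc[np.asarray(idx)].reset_index(drop=True))

    def validate_sorted_unique(self) -> None:
        """Require strictly increasing positions within chromosome and no
        duplicate (chrom, pos) — the post-QC invariant."""
        if not self.is_sorted():
            raise ValueError("marker map is not sorted by (chrom, pos)")
        for _, grp in self.df.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    "duplicate or non-increasing positions on "
                    f"chromosome {grp['chrom'].iloc[0]}"
                )

    def __eq__(self, other) -> bool:
        return isinstance(other, MarkerMap) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"MarkerMap(n_markers={self.n_markers})"


@dataclass
class HaplotypeSet:
    """Phased 0/1 allele matrix: rows are gametes (2 per individual)."""

    haplotypes: np.ndarray
    sample_ids: list[str]
    map: MarkerMap
    population_label: str = ""

    def __post_init__(self):
        h = np.ascontiguousarray(np.asarray(self.haplotypes, dtype=np.uint8))
        if h.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if h.shape[0] % 2 != 0:
            raise ValueError("haplotype row count must be even (2 per individual)")
        if h.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("row count must equal 2 x number of sample ids")
        if h.shape[1] != self.map.n_markers:
            raise ValueError("column count must equal marker map length")
        if h.size and h.max() > 1:
            raise ValueError("haplotype entries must be 0/1")
        self.haplotypes = h
        self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def allele1_freq(self) -> np.ndarray:
        """Frequency of the allele coded 1 (= allele1 of the map) per marker."""
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele1_freq()
        return np.minimum(p, 1.0 - p)

    def select_markers(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypeSet(
            self.haplotypes[:, idx],
            list(self.sample_ids),
            self.map.subset(idx),
            self.population_label,
        )

    def select_individuals(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypeSet(
            self.haplotypes[rows],
            [self.sample_ids[i] for i in idx],
            self.map,
            self.population_label,
        )

    def sorted_by_position(self) -> "HaplotypeSet":
        if self.map.is_sorted():
            return self
        order = self.map.sort_order()
        return self.select_markers(order)

    def to_genotypes(self) -> "GenotypeSet":
        g = (
            self.haplotypes[0::2].astype(np.int8)
            + self.haplotypes[1::2].astype(np.int8)
        )
        return GenotypeSet(g, list(self.sample_ids), self.map)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HaplotypeSet)
            and np.array_equal(self.haplotypes, other.haplotypes)
            and self.sample_ids == other.sample_ids
            and self.map == other.map
            and self.population_label == other.population_label
        )


@dataclass
class GenotypeSet:
    """Unphased genotype dosages {0,1,2} with -1 for missing; QC substrate."""

    genotypes: np.ndarray
    sample_ids: list[str]
    map: MarkerMap

    def __post_init__(self):
        g = np.ascontiguousarray(np.asarray(self.genotypes, dtype=np.int8))
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if g.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal number of sample ids")
        if g.shape[1] != self.map.n_markers:
            raise ValueError("column count must equal marker map length")
        if g.size and (g.max() > 2 or g.min() < -1):
            raise ValueError("genotype entries must be in {-1,0,1,2}")
        self.genotypes = g
        self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def called_mask(self) -> np.ndarray:
        return self.genotypes >= 0

    def select_samples(self, idx) -> "GenotypeSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeSet(
            self.genotypes[idx], [self.sample_ids[i] for i in idx], self.map
        )

    def select_markers(self, idx) -> "GenotypeSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeSet(
            self.genotypes[:, idx], list(self.sample_ids), self.map.subset(idx)
        )


# ---------------------------------------------------------------------------
# VCF I/O


def read_phased_vcf(
    path: str | os.PathLike,
    population_label: str = "",
    autosomes: Sequence[str] | None = None,
) -> HaplotypeSet:
    """Read a phased VCF into a :class:`HaplotypeSet`.

    Allele code 1 is the VCF ALT allele (map ``allele1`` = ALT, ``allele2`` =
    REF).  Records are sorted deterministically by (chromosome, position).

    Parameters
    ----------
    autosomes : sequence of str, optional
        If given, only records on these contigs are kept.

    Raises
    ------
    ValueError
        On an unphased genotype ("/"-separated), a missing allele, or a
        multiallelic record — naming the first offending record.
    """
    from cyvcf2 import VCF

    keep = set(map(str, autosomes)) if autosomes is not None else None
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows = []
    alleles = []
    for v in vcf:
        if keep is not None and str(v.CHROM) not in keep:
            continue
        if v.ALT is None or len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic or invalid record at {v.CHROM}:{v.POS}"
            )
        gts = v.genotypes  # list of [a0, a1, phased]
        col = np.empty(2 * len(samples), dtype=np.int16)
        for i, gt in enumerate(gts):
            if len(gt) < 3:
                raise ValueError(
                    f"haploid genotype at {v.CHROM}:{v.POS} sample {samples[i]}"
                )
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype at {v.CHROM}:{v.POS} sample {samples[i]};"
                    " impute and phase upstream"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS} sample {samples[i]}"
                )
            col[2 * i] = a0
            col[2 * i + 1] = a1
        rows.append(
            (str(v.CHROM), int(v.POS), v.ID if v.ID else f"{v.CHROM}:{v.POS}", col)
        )
        alleles.append((str(v.ALT[0]), str(v.REF)))
    vcf.close()
    if not rows:
        raise ValueError(f"no usable records in {path}")
    map_df = pd.DataFrame(
        {
            "snp_id": [r[2] for r in rows],
            "chrom": [r[0] for r in rows],
            "pos_bp": [r[1] for r in rows],
            "allele1": [a[0] for a in alleles],
            "allele2": [a[1] for a in alleles],
        }
    )
    mmap = MarkerMap(map_df)
    H = np.stack([r[3] for r in rows], axis=1).astype(np.uint8)
    hs = HaplotypeSet(H, samples, mmap, population_label)
    return hs.sorted_by_position()


def write_phased_vcf(h: HaplotypeSet, path: str | os.PathLike) -> None:
    """Write a :class:`HaplotypeSet` as a minimal phased VCF (4.2 text).

    REF = allele2, ALT = allele1 (the code-1 allele), matching the
    convention of :func:`read_phased_vcf` so write→read round-trips.
    """
    h = h.sorted_by_position()
    df = h.map.df
    contigs = list(dict.fromkeys(df["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldscape\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(h.sample_ids)
            + "\n"
        )
        H = h.haplotypes
        for j in range(h.n_markers):
            rec = df.iloc[j]
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(h.n_individuals)
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos_bp}\t{rec.snp_id}\t{rec.allele2}\t"
                f"{rec.allele1}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Plain-text haplotype matrix + map table


def write_haplotype_table(
    h: HaplotypeSet, hap_path: str | os.PathLike, map_path: str | os.PathLike
) -> None:
    """Write one row per gamete (whitespace-separated 0/1) plus a map TSV."""
    np.savetxt(hap_path, h.haplotypes, fmt="%d", delimiter=" ")
    h.map.df.to_csv(map_path, sep="\t", index=False)


def read_haplotype_table(
    hap_path: str | os.PathLike,
    map_path: str | os.PathLike,
    sample_ids: Sequence[str] | None = None,
    population_label: str = "",
) -> HaplotypeSet:
    H = np.loadtxt(hap_path, dtype=np.uint8, ndmin=2)
    mmap = MarkerMap(pd.read_csv(map_path, sep="\t"))
    if sample_ids is None:
        sample_ids = [f"ind{i + 1}" for i in range(H.shape[0] // 2)]
    return HaplotypeSet(H, list(sample_ids), mmap, population_label).sorted_by_position()


# ---------------------------------------------------------------------------
# Result tables


def write_table(
    df: pd.DataFrame, path: str | os.PathLike, float_format: str = "%.6f"
) -> None:
    """Write a result table as TSV with fixed float precision.

    Deterministic: the same DataFrame always produces byte-identical output.
    """
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_tables(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | os.PathLike,
    float_format: str = "%.6f",
) -> list[str]:
    """Write a dict of stage outputs as ``<out_dir>/<name>.tsv``.

    Returns the list of paths written, in input order.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, df in results.items():
        p = os.path.join(out_dir, f"{name}.tsv")
        write_table(df, p, float_format=float_format)
        paths.append(p)
    return paths
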