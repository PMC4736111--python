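"""Sample and marker quality control for SNP-array genotypes.

Replicates the standard array-QC filter set for diploid autosomal data:
samples are removed for low call rate, outlying heterozygosity and duplicate
genotypes; markers for non-autosomal location, low call rate, low MAF,
Hardy–Weinberg violation and duplicated map position (keeping the
highest-MAF SNP).  Filters are applied in a fixed order — samples first, then
markers — and every removal is accounted for in a :class:`QCReport` whose
bookkeeping identity (removed + retained = input) holds on every input.

A record failing several rules is counted once, under the first rule applied;
the number of such multi-rule failures is reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popdata import DEFAULT_AUTOSOMES, GenotypeSet


@dataclass
class QCThresholds:
    """Filter thresholds; defaults are the conventional array-QC values."""

    sample_call_rate_min: float = 0.90
    het_sd_limit: float = 3.0
    marker_call_rate_min: float = 0.98
    maf_min: float = 0.03
    hwe_p_min: float = 1e-6
    duplicate_concordance_min: float = 0.95
    hwe_test: str = "chisq"  # or "exact"

    def __post_init__(self):
        for name in (
            "sample_call_rate_min",
            "marker_call_rate_min",
            "maf_min",
            "hwe_p_min",
            "duplicate_concordance_min",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.het_sd_limit <= 0:
            raise ValueError("het_sd_limit must be > 0")
        if self.hwe_test not in ("chisq", "exact"):
            raise ValueError("hwe_test must be 'chisq' or 'exact'")


@dataclass
class QCReport:
    """Per-rule exclusion counts plus retained totals."""

    samples_removed: dict[str, int] = field(default_factory=dict)
    markers_removed: dict[str, int] = field(default_factory=dict)
    n_samples_in: int = 0
    n_samples_retained: int = 0
    n_markers_in: int = 0
    n_markers_retained: int = 0
    n_multi_rule_samples: int = 0
    removed_sample_ids: dict[str, list[str]] = field(default_factory=dict)
    removed_marker_ids: dict[str, list[str]] = field(default_factory=dict)

    def check_identity(self) -> None:
        if self.n_samples_in:
            assert (
                sum(self.samples_removed.values()) + self.n_samples_retained
                == self.n_samples_in
            ), "sample bookkeeping identity violated"
        if self.n_markers_in:
            assert (
                sum(self.markers_removed.values()) + self.n_markers_retained
                == self.n_markers_in
            ), "marker bookkeeping identity violated"

    def merged_with(self, other: "QCReport") -> "QCReport":
        out = QCReport(
            samples_removed={**self.samples_removed, **other.samples_removed},
            markers_removed={**self.markers_removed, **other.markers_removed},
            n_samples_in=self.n_samples_in or other.n_samples_in,
            n_samples_retained=other.n_samples_retained or self.n_samples_retained,
            n_markers_in=self.n_markers_in or other.n_markers_in,
            n_markers_retained=other.n_markers_retained or self.n_markers_retained,
            n_multi_rule_samples=self.n_multi_rule_samples
            + other.n_multi_rule_samples,
            removed_sample_ids={**self.removed_sample_ids, **other.removed_sample_ids},
            removed_marker_ids={**self.removed_marker_ids, **other.removed_marker_ids},
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples", "input", self.n_samples_in)]
        rows += [("samples", f"removed:{k}", v) for k, v in self.samples_removed.items()]
        rows += [
            ("samples", "multi_rule_failures", self.n_multi_rule_samples),
            ("samples", "retained", self.n_samples_retained),
            ("markers", "input", self.n_markers_in),
        ]
        rows += [("markers", f"removed:{k}", v) for k, v in self.markers_removed.items()]
        rows.append(("markers", "retained", self.n_markers_retained))
        return pd.DataFrame(rows, columns=["axis", "rule", "count"])


# ---------------------------------------------------------------------------
# Hardy–Weinberg


def hwe_pvalue(n_AA: int, n_Aa: int, n_aa: int, test: str = "chisq") -> float:
    """Hardy–Weinberg test p-value from genotype counts.

    Default is the Pearson chi-square goodness-of-fit with 1 df against
    expected counts from the sample allele frequency (upper-tail p).  A
    monomorphic marker returns p = 1 by convention (no test possible).
    ``test="exact"`` uses the exact conditional test on the heterozygote
    count (Wigginton-style mid-less two-sided p).
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("at least one genotype required")
    n_A = 2 * n_AA + n_Aa
    if n_A == 0 or n_A == 2 * n:
        return 1.0
    if test == "exact":
        return _hwe_exact(n_AA, n_Aa, n_aa)
    p = n_A / (2 * n)
    exp = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE test: P(het count as or less probable than observed),
    conditional on allele counts."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    rare = min(n_A, n_a)
    het_obs = n_Aa
    hets = np.arange(rare % 2, rare + 1, 2)
    # log-probabilities of each possible heterozygote count
    from scipy.special import gammaln

    def logp(h):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        return (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_r + 1)
            - gammaln(hom_c + 1)
            + gammaln(n_A + 1)
            + gammaln(n_a + 1)
            - gammaln(2 * n + 1)
        )

    lps = np.array([logp(int(h)) for h in hets])
    ps = np.exp(lps - lps.max())
    ps /= ps.sum()
    p_obs = ps[hets == het_obs][0]
    return float(min(1.0, ps[ps <= p_obs + 1e-12].sum()))


def hwe_pvalues(g: GenotypeSet, test: str = "chisq") -> np.ndarray:
    """Vector of HWE p-values, one per marker, from called genotypes."""
    G = g.genotypes
    called = G >= 0
    n_AA = ((G == 2) & called).sum(axis=0)
    n_Aa = (G == 1).sum(axis=0)
    n_aa = (G == 0).sum(axis=0)
    if test == "chisq":
        n = n_AA + n_Aa + n_aa
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (2 * n_AA + n_Aa) / (2 * n)
            exp_AA = p * p * n
            exp_Aa = 2 * p * (1 - p) * n
            exp_aa = (1 - p) ** 2 * n
            chi2 = (
                (n_AA - exp_AA) ** 2 / exp_AA
                + (n_Aa - exp_Aa) ** 2 / exp_Aa
                + (n_aa - exp_aa) ** 2 / exp_aa
            )
        out = stats.chi2.sf(chi2, df=1)
        mono = (p <= 0) | (p >= 1) | (n == 0)
        out = np.where(mono, 1.0, out)
        return out
    return np.array(
        [hwe_pvalue(int(a), int(b), int(c), test=test) for a, b, c in zip(n_AA, n_Aa, n_aa)]
    )


# ---------------------------------------------------------------------------
# helpers


def sample_call_rate(g: GenotypeSet) -> np.ndarray:
    return g.called_mask().mean(axis=1)


def marker_call_rate(g: GenotypeSet) -> np.ndarray:
    return g.called_mask().mean(axis=0)


def marker_maf(g: GenotypeSet) -> np.ndarray:
    G = g.genotypes
    called = G >= 0
    n_called = called.sum(axis=0)
    dose = np.where(called, G, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = dose / (2 * n_called)
    p = np.where(n_called == 0, 0.0, p)
    return np.minimum(p, 1 - p)


def sample_heterozygosity(g: GenotypeSet) -> np.ndarray:
    """Proportion heterozygous among called genotypes, per sample."""
    G = g.genotypes
    called = G >= 0
    n_called = called.sum(axis=1)
    n_het = (G == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = n_het / n_called
    return np.where(n_called == 0, np.nan, h)


def _pairwise_concordance(G: np.ndarray, i: int, j: int) -> float:
    both = (G[i] >= 0) & (G[j] >= 0)
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float((G[i, both] == G[j, both]).mean())


# ---------------------------------------------------------------------------
# sample QC


def sample_qc(
    g: GenotypeSet, thr: QCThresholds | None = None
) -> tuple[GenotypeSet, QCReport]:
    """Sample filters, applied in order: call rate, heterozygosity outliers
    (mean ± ``het_sd_limit``·SD over samples surviving the call-rate filter),
    duplicate genotypes (concordance >= threshold at jointly-called markers;
    the lower-call-rate member of each duplicate pair is removed).
    """
    thr = thr or QCThresholds()
    rpt = QCReport(n_samples_in=g.n_samples, n_markers_in=g.n_markers)
    ids = np.array(g.sample_ids)

    cr = sample_call_rate(g)
    fail_cr = cr < thr.sample_call_rate_min

    # heterozygosity on call-rate survivors
    keep1 = ~fail_cr
    fail_het = np.zeros(g.n_samples, dtype=bool)
    if keep1.sum() < 3:
        warnings.warn(
            "fewer than 3 samples after call-rate filter; "
            "heterozygosity filter skipped"
        )
    else:
        het = sample_heterozygosity(g)
        mu = float(np.nanmean(het[keep1]))
        sd = float(np.nanstd(het[keep1], ddof=1))
        if sd > 0:
            fail_het = keep1 & (np.abs(het - mu) > thr.het_sd_limit * sd)

    # duplicates among survivors of the first two filters
    keep2 = keep1 & ~fail_het
    fail_dup = np.zeros(g.n_samples, dtype=bool)
    surv = np.flatnonzero(keep2)
    G = g.genotypes
    for a in range(len(surv)):
        for b in range(a + 1, len(surv)):
            i, j = surv[a], surv[b]
            if fail_dup[i] or fail_dup[j]:
                continue
            if _pairwise_concordance(G, i, j) >= thr.duplicate_concordance_min:
                drop = i if cr[i] < cr[j] else j  # ties: keep the earlier sample
                fail_dup[drop] = True

    # multiplicity: removed samples failing >1 rule evaluated on the input
    n_multi = int(np.sum((fail_cr.astype(int) + fail_het + fail_dup) > 1))

    rpt.samples_removed = {
        "call_rate": int(fail_cr.sum()),
        "heterozygosity": int(fail_het.sum()),
        "duplicate": int(fail_dup.sum()),
    }
    rpt.removed_sample_ids = {
        "call_rate": list(ids[fail_cr]),
        "heterozygosity": list(ids[fail_het]),
        "duplicate": list(ids[fail_dup]),
    }
    rpt.n_multi_rule_samples = n_multi
    keep = keep2 & ~fail_dup
    out = g.select_samples(keep)
    rpt.n_samples_retained = out.n_samples
    rpt.n_markers_retained = out.n_markers
    rpt.check_identity()
    return out, rpt


# ---------------------------------------------------------------------------
# marker QC


def marker_qc(
    g: GenotypeSet,
    thr: QCThresholds | None = None,
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES,
    drop_monomorphic: bool = False,
) -> tuple[GenotypeSet, QCReport]:
    """Marker filters, applied in order: autosome restriction, call rate,
    MAF, HWE, duplicate-position resolution (highest-MAF SNP retained),
    optional monomorphic removal.

    ``sample_qc`` is expected to have been applied first (fixed order).
    """
    thr = thr or QCThresholds()
    rpt = QCReport(n_samples_in=g.n_samples, n_markers_in=g.n_markers)
    removed: dict[str, int] = {}
    removed_ids: dict[str, list[str]] = {}

    def drop(rule: str, fail_mask: np.ndarray, cur: GenotypeSet) -> GenotypeSet:
        removed[rule] = int(fail_mask.sum())
        removed_ids[rule] = list(cur.map.snp_id[fail_mask])
        return cur.select_markers(~fail_mask)

    cur = g
    auto = set(autosomes)
    cur = drop("non_autosomal", ~np.isin(cur.map.chrom, list(auto)), cur)
    cur = drop("call_rate", marker_call_rate(cur) < thr.marker_call_rate_min, cur)
    cur = drop("maf", marker_maf(cur) < thr.maf_min, cur)
    cur = drop("hwe", hwe_pvalues(cur, test=thr.hwe_test) < thr.hwe_p_min, cur)

    # duplicate positions: keep the highest-MAF SNP at each (chrom, pos)
    maf = marker_maf(cur)
    dfpos = pd.DataFrame(
        {"chrom": cur.map.chrom, "pos": cur.map.pos_bp, "maf": maf}
    )
    # stable: among equal MAF keep the first-listed SNP
    best = (
        dfpos.sort_values("maf", kind="stable", ascending=False)
        .groupby(["chrom", "pos"], sort=False)
        .head(1)
        .index
    )
    fail_duppos = ~dfpos.index.isin(best)
    cur = drop("duplicate_position", fail_duppos.to_numpy() if hasattr(fail_duppos, "to_numpy") else np.asarray(fail_duppos), cur)

    if drop_monomorphic:
        cur = drop("monomorphic", marker_maf(cur) <= 0.0, cur)

    rpt.markers_removed = removed
    rpt.removed_marker_ids = removed_ids
    rpt.n_markers_retained = cur.n_markers
    rpt.n_samples_retained = cur.n_samples
    rpt.check_identity()
    return cur, rpt


def run_qc(
    g: GenotypeSet,
    thr: QCThresholds | None = None,
    autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES,
    drop_monomorphic: bool = False,
) -> tuple[GenotypeSet, QCReport]:
    """Full QC: sample filters, then marker filters, with a merged report."""
    thr = thr or QCThresholds()
    g1, rpt_s = sample_qc(g, thr)
    g2, rpt_m = marker_qc(g1, thr, autosomes=autosomes, drop_monomorphic=drop_monomorphic)
    rpt = rpt_s.merged_with(rpt_m)
    rpt.n_samples_in = g.n_samples
    rpt.n_markers_in = g.n_markers
    rpt.n_samples_retained = g2.n_samples
    rpt.n_markers_retained = g2.n_markers
    rpt.check_identity()
    return g2, rpt
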