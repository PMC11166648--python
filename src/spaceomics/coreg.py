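"""Expression normalization, z-scoring, pathway trajectories, co-regulation
testing, dual-quantifier concordance, and the consensus differential
expression rule.

The longitudinal design has few subjects (four) but seven timepoints per
subject, so gene-level inference is noisy and the unit of interest is the
*pathway*: a curated gene set whose members move together. After library-size
normalization (counts per million) and per-gene z-scoring of log2(CPM+1)
across all samples, a pathway's co-regulation score is the variance of its
member-mean profile,

    score(P) = sum_s m_s**2,   m_s = mean over member genes g of z[g, s],

which is large when member genes rise and fall together across samples and
near zero when they cancel. Significance comes from a permutation null of
random same-size gene sets drawn from the detected-gene universe, with
Benjamini–Hochberg adjustment across pathways.

Because the study quantified expression with two independent pipelines (one
discarding multi-mapped reads, one distributing them fractionally), the
module also provides their reconciliation: per-gene count averaging for
pathway analysis, per-sample/per-gene concordance metrics, and the
dual-quantifier consensus rule under which a gene is differentially
expressed only if both pipelines call it so at FDR < alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io import CountMatrix, FormatError, GeneSetDB, SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "ZMatrix",
    "PathwayTrajectory",
    "CoregResult",
    "ConcordanceResult",
    "normalize_library_size",
    "average_quantifiers",
    "zscore",
    "pathway_trajectory",
    "coregulation_test",
    "concordance",
    "genes_detected",
    "simple_de",
]


def normalize_library_size(counts: CountMatrix, scale: float = 1e6) -> CountMatrix:
    """Scale each sample's counts to a fixed column total (CPM semantics)."""
    sizes = counts.library_sizes()
    zero = sizes.index[sizes <= 0]
    if len(zero):
        raise FormatError(
            f"cannot normalize: sample(s) with zero library size: {list(zero)}"
        )
    return CountMatrix(counts.data * (scale / sizes))


def average_quantifiers(
    counts_a: CountMatrix, counts_b: CountMatrix
) -> tuple[CountMatrix, list[str]]:
    """Per-gene mean of two quantifiers' counts on their shared gene universe.

    Sample ids must match exactly; gene universes may differ, and genes
    outside the intersection are excluded and returned as the second element.
    """
    if counts_a.sample_ids != counts_b.sample_ids:
        raise FormatError(
            "sample ids differ between quantifiers: "
            f"{counts_a.sample_ids} vs {counts_b.sample_ids}"
        )
    shared = [g for g in counts_a.gene_ids if g in set(counts_b.gene_ids)]
    dropped = sorted(
        (set(counts_a.gene_ids) | set(counts_b.gene_ids)) - set(shared)
    )
    if dropped:
        logger.warning(
            "average_quantifiers: %d gene(s) outside the intersection "
            "excluded: %s%s",
            len(dropped), dropped[:10], "..." if len(dropped) > 10 else "",
        )
    if not shared:
        raise FormatError("no shared genes between quantifiers")
    avg = (counts_a.data.loc[shared] + counts_b.data.loc[shared]) / 2.0
    return CountMatrix(avg), dropped


@dataclass
class ZMatrix:
    """Per-gene z-scores across samples; zero-variance genes are set aside.

    Every retained row has mean 0 and sample SD (n-1 denominator) 1.
    """

    z: pd.DataFrame
    constant_genes: frozenset[str] = field(default_factory=frozenset)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


def zscore(
    norm_counts: CountMatrix,
    log_transform: bool = True,
    pseudocount: float = 1.0,
    ddof: int = 1,
) -> ZMatrix:
    """z-score each gene across samples, on log2(value+pseudocount) by default.

    The log transform stabilizes the strong mean-variance coupling of count
    data before standardization. SD uses the n-1 (sample) denominator.
    Genes with zero variance carry no longitudinal signal and are moved to
    ``constant_genes`` rather than producing 0/0 rows.
    """
    if norm_counts.shape[1] < 2:
        raise FormatError("z-scores are undefined for a single-sample matrix")
    x = norm_counts.data
    if log_transform:
        x = np.log2(x + pseudocount)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=ddof)
    constant = frozenset(x.index[sd == 0])
    keep = x.index[sd > 0]
    z = x.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    if constant:
        logger.info("zscore: %d constant gene(s) excluded", len(constant))
    return ZMatrix(z=z, constant_genes=constant)


@dataclass
class PathwayTrajectory:
    """Median member-gene z per timepoint for one pathway.

    Timepoints are ordered by signed day; ``n_values`` counts the
    (gene x subject) observations pooled into each median.
    """

    pathway: str
    timepoint_labels: list[str]
    time_days: list[int]
    median_z: list[float]
    n_values: list[int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timepoint": self.timepoint_labels,
                "time_days": self.time_days,
                "median_z": self.median_z,
                "n_values": self.n_values,
            }
        )


def pathway_trajectory(
    zmat: ZMatrix,
    geneset: frozenset[str] | set[str],
    sample_meta: list[SampleMeta],
    pathway: str = "",
    average_subjects_first: bool = False,
) -> PathwayTrajectory:
    """Median z of a pathway's member genes at each timepoint.

    By default the median pools every (member gene, subject) z value at a
    timepoint; ``average_subjects_first=True`` instead takes each gene's mean
    across subjects before the median over genes.
    """
    members = [g for g in zmat.gene_ids if g in geneset]
    if not members:
        raise FormatError(f"pathway {pathway!r} not detected: no member genes in matrix")
    by_sample = {m.sample_id: m for m in sample_meta}
    missing = [s for s in zmat.sample_ids if s not in by_sample]
    if missing:
        raise FormatError(f"sample sheet lacks z-matrix samples: {missing}")
    days_present = sorted(
        {by_sample[s].time_days for s in zmat.sample_ids}
    )
    labels, meds, ns = [], [], []
    sub = zmat.z.loc[members]
    for day in days_present:
        cols = [s for s in zmat.sample_ids if by_sample[s].time_days == day]
        labels.append(by_sample[cols[0]].timepoint_label)
        block = sub[cols]
        if average_subjects_first:
            vals = block.mean(axis=1).to_numpy()
        else:
            vals = block.to_numpy().ravel()
        meds.append(float(np.median(vals)))
        ns.append(int(vals.size))
    return PathwayTrajectory(
        pathway=pathway,
        timepoint_labels=labels,
        time_days=days_present,
        median_z=meds,
        n_values=ns,
    )


def _random_subsets(
    rng: np.random.Generator, n: int, k: int, n_draws: int
) -> np.ndarray:
    """``n_draws`` independent uniform k-subsets of range(n), one per row.

    Rejection-samples ordered k-tuples until duplicate-free (uniform over
    subsets since every subset admits the same number of orderings); falls
    back to argpartition of random keys when collisions would dominate.
    """
    if k > n:
        raise ValueError(f"cannot draw {k}-subsets from {n} genes")
    if k * k > n:  # birthday regime: rejection would thrash
        keys = rng.random((n_draws, n))
        return np.argpartition(keys, k - 1, axis=1)[:, :k]
    idx = rng.integers(0, n, size=(n_draws, k))
    while True:
        s = np.sort(idx, axis=1)
        bad = (s[:, 1:] == s[:, :-1]).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), k))


@dataclass(frozen=True)
class CoregResult:
    pathway: str
    score: float
    p: float
    padj: float
    n_genes_used: int


def coregulation_test(
    zmat: ZMatrix,
    geneset_db: GeneSetDB,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int | None = None,
) -> tuple[list[CoregResult], list[str]]:
    """Permutation test of pathway co-regulation on a z-matrix.

    For each pathway P with between ``min_size`` and ``max_size`` detected
    member genes, score(P) = sum over samples of the squared member-mean z.
    The null draws ``n_perm`` uniform random gene sets of the same size from
    the detected-gene universe; p = (1 + #{null >= observed}) / (n_perm + 1),
    so p >= 1/(n_perm+1) always. BH adjustment runs across tested pathways.

    Returns (results sorted by ascending p, names of skipped pathways).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >=100, got {n_perm}")
    rng = np.random.default_rng(seed)
    zvals = zmat.z.to_numpy()
    n_genes = zvals.shape[0]
    index_of = {g: i for i, g in enumerate(zmat.gene_ids)}

    member_idx: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for name, genes in geneset_db.items():
        idx = np.array([index_of[g] for g in genes if g in index_of], dtype=int)
        if min_size <= len(idx) <= max_size:
            member_idx[name] = idx
        else:
            skipped.append(name)
            logger.info(
                "coregulation_test: skipping %s (%d detected genes outside "
                "[%d, %d])", name, len(idx), min_size, max_size,
            )

    results = []
    for name, idx in member_idx.items():
        k = len(idx)
        m_obs = zvals[idx].mean(axis=0)
        score = float((m_obs**2).sum())
        null_members = _random_subsets(rng, n_genes, k, n_perm)
        null_m = zvals[null_members].mean(axis=1)        # (n_perm, n_samples)
        null_scores = (null_m**2).sum(axis=1)
        p = (1.0 + float((null_scores >= score).sum())) / (n_perm + 1.0)
        results.append((name, score, p, k))

    padj = bh_adjust(np.array([r[2] for r in results]))
    out = [
        CoregResult(pathway=n, score=s, p=p, padj=float(q), n_genes_used=k)
        for (n, s, p, k), q in zip(results, padj)
    ]
    out.sort(key=lambda r: (r.p, r.pathway))
    return out, skipped


@dataclass
class ConcordanceResult:
    """Agreement between two quantifier/DE pipelines on shared genes."""

    per_sample_r: pd.Series        # Pearson r of log2(count+1), per sample
    median_r: float
    log2fc_r: float                # Pearson r of log2 fold changes
    categories: pd.Series          # gene -> both | only_A | only_B | neither
    consensus_degs: frozenset[str]


def _dge_frame(dge: pd.DataFrame) -> pd.DataFrame:
    need = {"gene", "log2fc", "p", "padj"}
    missing = need - set(dge.columns)
    if missing:
        raise FormatError(f"DGE table missing column(s): {sorted(missing)}")
    if dge["gene"].duplicated().any():
        dup = dge.loc[dge["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"DGE table has duplicate gene {dup!r}")
    return dge.set_index("gene")


def concordance(
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    dge_a: pd.DataFrame,
    dge_b: pd.DataFrame,
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Quantifier concordance and the dual-pipeline consensus DEG set.

    The gene universe is the intersection of both quantifiers' reported
    genes. A gene is a consensus DEG iff padj < alpha in *both* DGE tables;
    the significance categories (both / only_A / only_B / neither) partition
    the shared DGE universe.
    """
    shared_samples = [s for s in counts_a.sample_ids if s in set(counts_b.sample_ids)]
    shared_genes = [g for g in counts_a.gene_ids if g in set(counts_b.gene_ids)]
    if not shared_samples or not shared_genes:
        raise FormatError("empty sample or gene intersection between quantifiers")
    la = np.log2(counts_a.data.loc[shared_genes, shared_samples] + 1)
    lb = np.log2(counts_b.data.loc[shared_genes, shared_samples] + 1)
    rs = {}
    for s in shared_samples:
        a, b = la[s].to_numpy(), lb[s].to_numpy()
        if a.std() == 0 or b.std() == 0:
            rs[s] = math.nan
        elif np.array_equal(a, b):
            rs[s] = 1.0  # identical data correlate exactly, no rounding
        else:
            rs[s] = float(np.corrcoef(a, b)[0, 1])
    per_sample_r = pd.Series(rs, name="pearson_r")
    median_r = float(per_sample_r.median())

    da, db = _dge_frame(dge_a), _dge_frame(dge_b)
    dge_genes = da.index.intersection(db.index)
    finite = (
        np.isfinite(da.loc[dge_genes, "log2fc"])
        & np.isfinite(db.loc[dge_genes, "log2fc"])
    )
    fa = da.loc[dge_genes[finite], "log2fc"].to_numpy()
    fb = db.loc[dge_genes[finite], "log2fc"].to_numpy()
    if len(fa) >= 2 and fa.std() > 0 and fb.std() > 0:
        log2fc_r = float(np.corrcoef(fa, fb)[0, 1])
    else:
        log2fc_r = math.nan

    sig_a = da.loc[dge_genes, "padj"] < alpha
    sig_b = db.loc[dge_genes, "padj"] < alpha
    cat = pd.Series("neither", index=dge_genes, name="category")
    cat[sig_a & sig_b] = "both"
    cat[sig_a & ~sig_b] = "only_A"
    cat[~sig_a & sig_b] = "only_B"
    consensus = frozenset(dge_genes[(sig_a & sig_b).to_numpy()])
    return ConcordanceResult(
        per_sample_r=per_sample_r,
        median_r=median_r,
        log2fc_r=log2fc_r,
        categories=cat,
        consensus_degs=consensus,
    )


def genes_detected(counts: CountMatrix, min_alignments: float = 10) -> pd.Series:
    """Per-sample count of genes with strictly more than ``min_alignments``."""
    return (counts.data > min_alignments).sum(axis=0)


def simple_de(
    counts: CountMatrix,
    group_test: list[str],
    group_ref: list[str],
    subject_blocks: dict[str, str] | None = None,
    source: str = "simple_de",
) -> pd.DataFrame:
    """Self-contained two-group differential expression on log2(CPM+1).

    Per gene, log2fc is the mean log2(CPM+1) difference (test - ref). When
    ``subject_blocks`` assigns every subject at least one sample in each
    group, p comes from a two-sided paired t-test on per-subject group-mean
    differences; otherwise from Welch's unpaired t-test. padj is BH. Genes
    with no variance get p = 1.

    This is a deliberately simple location test — no dispersion shrinkage or
    GLM machinery — intended for synthetic studies and sanity checks, not as
    a replacement for a count-model DE engine on real data.
    """
    for name, grp in (("test", group_test), ("ref", group_ref)):
        if len(grp) < 2:
            raise FormatError(f"group_{name} needs >=2 samples, got {len(grp)}")
    cpm = normalize_library_size(counts.subset_samples([*group_test, *group_ref]))
    logx = np.log2(cpm.data + 1)
    xt, xr = logx[group_test], logx[group_ref]
    log2fc = xt.mean(axis=1) - xr.mean(axis=1)

    paired = False
    if subject_blocks is not None:
        subj_t = {subject_blocks[s] for s in group_test}
        subj_r = {subject_blocks[s] for s in group_ref}
        paired = subj_t == subj_r and len(subj_t) >= 2
    if paired:
        subjects = sorted({subject_blocks[s] for s in group_test})
        dt = np.column_stack(
            [
                xt[[s for s in group_test if subject_blocks[s] == subj]].mean(axis=1)
                - xr[[s for s in group_ref if subject_blocks[s] == subj]].mean(axis=1)
                for subj in subjects
            ]
        )
        res = stats.ttest_1samp(dt, popmean=0.0, axis=1)
    else:
        res = stats.ttest_ind(
            xt.to_numpy(), xr.to_numpy(), axis=1, equal_var=False
        )
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = pd.DataFrame(
        {
            "gene": logx.index,
            "log2fc": log2fc.to_numpy(),
            "p": p,
            "padj": bh_adjust(p),
            "source": source,
        }
    )
    return out.reset_index(drop=True)
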