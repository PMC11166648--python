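"""Site-level differential m6A methylation and its downstream summaries.

Direct-RNA site callers report, per candidate adenosine site and per sample,
how many reads covered the site and how many carried the m6A modification.
This module tests each site for a difference in methylation fraction between
two sample groups (e.g. the day-after-return draw vs all pre-flight draws),
controls FDR across sites, classifies significant sites as hyper- or
hypomethylated, and then asks three follow-up questions:

* **reversal** — which sites that spiked at return significantly relax back
  toward baseline at the recovery draws (and on which genes);
* **pathway density** — differentially methylated sites per detected gene,
  per pathway, the methylation analogue of expression co-regulation;
* **overlap** — how much the differentially methylated gene set intersects
  the differentially expressed gene set.

m6A occurs in a DRACH 5-mer context (D = A/G/U, R = A/G, then the methylated
A, then C, H = A/C/U); :func:`drach_check` implements that consensus with T
and U interchangeable.

Two test engines are provided. ``pooled`` sums (modified, unmodified) reads
within each group and applies a two-sided Fisher exact test to the 2x2
table. ``logistic`` is a binomial likelihood-ratio test with a group
indicator, keeping per-sample totals separate; with a single binary
covariate the group MLEs are the pooled per-group proportions, so the LRT is
computed in closed form. The default uses the logistic engine when both
groups have at least two samples and falls back to pooled otherwise.
q-values are Benjamini–Hochberg across tested sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .io import FormatError, GeneSetDB

logger = logging.getLogger(__name__)

__all__ = [
    "MethSiteTable",
    "ProfileDef",
    "ReversalReport",
    "filter_coverage",
    "drach_check",
    "diff_methylation",
    "classify_profile",
    "reversal_analysis",
    "pathway_meth_density",
    "density_expression_correlation",
    "deg_meth_overlap",
    "read_meth_sites",
    "write_meth_sites",
]

REGIONS = ("exon", "UTR", "unknown")


@dataclass
class MethSiteTable:
    """Candidate m6A sites with per-sample (coverage, modified-read) counts.

    ``sites`` is indexed by site id with columns ``transcript_id``,
    ``gene_id``, ``position`` (0-based offset within the transcript),
    ``kmer`` (5-mer) and ``region``; ``coverage`` and ``mod`` are
    site x sample integer frames with 0 <= mod <= coverage everywhere.
    """

    sites: pd.DataFrame
    coverage: pd.DataFrame
    mod: pd.DataFrame

    def __post_init__(self) -> None:
        for name, frame in (("coverage", self.coverage), ("mod", self.mod)):
            if not frame.index.equals(self.sites.index):
                raise FormatError(f"{name} index differs from sites index")
        if not self.coverage.columns.equals(self.mod.columns):
            raise FormatError("coverage and mod sample columns differ")
        if self.sites.index.has_duplicates:
            dup = self.sites.index[self.sites.index.duplicated()][0]
            raise FormatError(f"duplicate site id {dup!r}")
        cov = self.coverage.to_numpy()
        mod = self.mod.to_numpy()
        if (cov < 0).any() or (mod < 0).any():
            raise FormatError("negative coverage or modified-read count")
        if (mod > cov).any():
            si, sa = np.argwhere(mod > cov)[0]
            raise FormatError(
                f"mod_reads > coverage at site {self.sites.index[si]!r}, "
                f"sample {self.coverage.columns[sa]!r}"
            )
        badk = self.sites.index[self.sites["kmer"].str.len() != 5]
        if len(badk):
            raise FormatError(f"non-5-mer kmer at site {badk[0]!r}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coverage.columns)

    def subset(self, site_ids) -> "MethSiteTable":
        idx = list(site_ids)
        return MethSiteTable(
            sites=self.sites.loc[idx],
            coverage=self.coverage.loc[idx],
            mod=self.mod.loc[idx],
        )


def read_meth_sites(path) -> MethSiteTable:
    """Read the site-table TSV written by :func:`write_meth_sites`.

    Layout: site_id, transcript_id, gene_id, position, kmer, region, then
    ``cov:<sample>`` and ``mod:<sample>`` column pairs.
    """
    df = pd.read_csv(path, sep="\t", index_col="site_id")
    meta_cols = ["transcript_id", "gene_id", "position", "kmer", "region"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    cov_cols = [c for c in df.columns if c.startswith("cov:")]
    mod_cols = [c for c in df.columns if c.startswith("mod:")]
    samples = [c[4:] for c in cov_cols]
    if samples != [c[4:] for c in mod_cols]:
        raise FormatError(f"{path}: cov:/mod: sample columns do not pair up")
    cov = df[cov_cols].astype(int)
    cov.columns = samples
    mod = df[mod_cols].astype(int)
    mod.columns = samples
    return MethSiteTable(sites=df[meta_cols], coverage=cov, mod=mod)


def write_meth_sites(table: MethSiteTable, path) -> None:
    out = table.sites.copy()
    for s in table.sample_ids:
        out[f"cov:{s}"] = table.coverage[s]
        out[f"mod:{s}"] = table.mod[s]
    out.to_csv(path, sep="\t", index_label="site_id")


def filter_coverage(
    table: MethSiteTable, min_cov: int = 20, samples: list[str] | None = None
) -> MethSiteTable:
    """Retain sites covered at >= ``min_cov`` reads in every listed sample.

    The per-sample rule (not a group mean) mirrors how site callers filter:
    one under-covered sample makes the site's group fraction unreliable.
    """
    if min_cov < 1:
        raise ValueError(f"min_cov must be >=1, got {min_cov}")
    cols = table.sample_ids if samples is None else list(samples)
    keep = (table.coverage[cols] >= min_cov).all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "filter_coverage: removed %d/%d sites below %dx in %d sample(s)",
            n_removed, len(keep), min_cov, len(cols),
        )
    return table.subset(table.sites.index[keep])


_D = frozenset("AGTU")
_R = frozenset("AG")
_H = frozenset("ACTU")
_ALPHABET = frozenset("ACGTU")


def drach_check(kmer: str) -> bool:
    """True iff a 5-mer matches the DRACH m6A consensus (T and U equivalent).

    Positions: D in {A,G,U}, R in {A,G}, A, C, H in {A,C,U}.
    """
    if len(kmer) != 5:
        raise ValueError(f"kmer must have length 5, got {kmer!r}")
    k = kmer.upper()
    bad = set(k) - _ALPHABET
    if bad:
        raise ValueError(f"kmer {kmer!r} has letters outside ACGTU: {sorted(bad)}")
    return (
        k[0] in _D and k[1] in _R and k[2] == "A" and k[3] == "C" and k[4] in _H
    )


def _binomial_lrt(
    mod_t: np.ndarray, cov_t: np.ndarray, mod_r: np.ndarray, cov_r: np.ndarray
) -> float:
    """Closed-form binomial LRT p for a group effect, per-sample totals kept.

    Equivalent to logistic regression of per-read modification status on a
    binary group indicator: the alternative's MLEs are the pooled per-group
    fractions, the null's is the overall fraction.
    """

    def ll(mod, cov, pi):
        pi = min(max(pi, 1e-12), 1 - 1e-12)
        return float(mod.sum()) * np.log(pi) + float((cov - mod).sum()) * np.log(1 - pi)

    ct, cr = cov_t.sum(), cov_r.sum()
    if ct == 0 or cr == 0:
        return 1.0
    pt, pr = mod_t.sum() / ct, mod_r.sum() / cr
    p0 = (mod_t.sum() + mod_r.sum()) / (ct + cr)
    lr = 2.0 * (
        ll(mod_t, cov_t, pt) + ll(mod_r, cov_r, pr)
        - ll(mod_t, cov_t, p0) - ll(mod_r, cov_r, p0)
    )
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def diff_methylation(
    table: MethSiteTable,
    test_samples: list[str],
    ref_samples: list[str],
    q_threshold: float = 0.01,
    engine: str = "auto",
) -> pd.DataFrame:
    """Per-site differential methylation between two sample groups.

    Returns a frame with one row per site: pooled group percentages
    (``pct_test``, ``pct_ref``), ``meth_diff`` = pct_test - pct_ref in
    percentage points, the test p, the BH q, ``significant`` (q below
    threshold) and ``direction`` (hyper / hypo / ns). The input should
    already be coverage-filtered.
    """
    if not test_samples or not ref_samples:
        raise FormatError("both sample groups must be nonempty")
    overlap = set(test_samples) & set(ref_samples)
    if overlap:
        raise FormatError(f"groups overlap: {sorted(overlap)}")
    if engine not in ("auto", "pooled", "logistic"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "auto":
        engine = (
            "logistic" if len(test_samples) >= 2 and len(ref_samples) >= 2
            else "pooled"
        )

    cov_t = table.coverage[test_samples].to_numpy()
    mod_t = table.mod[test_samples].to_numpy()
    cov_r = table.coverage[ref_samples].to_numpy()
    mod_r = table.mod[ref_samples].to_numpy()

    mt, ct = mod_t.sum(axis=1), cov_t.sum(axis=1)
    mr, cr = mod_r.sum(axis=1), cov_r.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pct_t = np.where(ct > 0, 100.0 * mt / np.maximum(ct, 1), np.nan)
        pct_r = np.where(cr > 0, 100.0 * mr / np.maximum(cr, 1), np.nan)
    meth_diff = pct_t - pct_r

    pvals = np.ones(len(table.sites))
    for i in range(len(pvals)):
        if ct[i] == 0 or cr[i] == 0:
            pvals[i] = np.nan
            continue
        if engine == "pooled":
            tab = [[mt[i], ct[i] - mt[i]], [mr[i], cr[i] - mr[i]]]
            pvals[i] = stats.fisher_exact(tab, alternative="two-sided")[1]
        else:
            pvals[i] = _binomial_lrt(mod_t[i], cov_t[i], mod_r[i], cov_r[i])

    q = bh_adjust(pvals)
    significant = (q < q_threshold) & ~np.isnan(q)
    direction = np.where(
        significant & (meth_diff > 0), "hyper",
        np.where(significant & (meth_diff < 0), "hypo", "ns"),
    )
    return pd.DataFrame(
        {
            "site_id": table.sites.index,
            "gene_id": table.sites["gene_id"].to_numpy(),
            "transcript_id": table.sites["transcript_id"].to_numpy(),
            "kmer": table.sites["kmer"].to_numpy(),
            "region": table.sites["region"].to_numpy(),
            "pct_test": pct_t,
            "pct_ref": pct_r,
            "meth_diff": meth_diff,
            "p": pvals,
            "q": q,
            "significant": significant,
            "direction": direction,
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class ProfileDef:
    """A named group contrast, e.g. FP1 = return vs all pre-flight draws."""

    name: str
    test_timepoints: tuple[str, ...]
    reference_timepoints: tuple[str, ...]

    def __post_init__(self) -> None:
        both = set(self.test_timepoints) & set(self.reference_timepoints)
        if both:
            raise FormatError(
                f"profile {self.name}: timepoints in both groups: {sorted(both)}"
            )


def classify_profile(records: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Partition one profile's significant sites by sign of meth_diff."""
    sig = records[records["significant"]]
    hyper = set(sig.loc[sig["meth_diff"] > 0, "site_id"])
    hypo = set(sig.loc[sig["meth_diff"] < 0, "site_id"])
    return hyper, hypo


@dataclass
class ReversalReport:
    """Sites whose return-day methylation shift relaxes during recovery.

    Per recovery day: hyper sites at return that significantly *decreased*
    in the recovery-vs-return contrast, and hypo sites that significantly
    *increased*; plus the deduplicated genes carrying them.
    """

    reversed_hyper: dict[str, set[str]] = field(default_factory=dict)
    reversed_hypo: dict[str, set[str]] = field(default_factory=dict)
    genes_hyper: dict[str, set[str]] = field(default_factory=dict)
    genes_hypo: dict[str, set[str]] = field(default_factory=dict)


def reversal_analysis(
    flight_records: pd.DataFrame,
    recovery_records_by_day: dict[str, pd.DataFrame],
) -> ReversalReport:
    """Cross the flight profile with each recovery-vs-return profile.

    ``flight_records`` must come from the return-vs-pre-flight contrast;
    each entry of ``recovery_records_by_day`` from a recovery-day-vs-return
    contrast (significance thresholds already applied by
    :func:`diff_methylation` within each profile's own test family).
    """
    if flight_records is None or not len(flight_records):
        raise FormatError("flight profile records are required")
    if not recovery_records_by_day:
        raise FormatError("at least one recovery profile is required")
    hyper, hypo = classify_profile(flight_records)
    gene_of = dict(zip(flight_records["site_id"], flight_records["gene_id"]))
    report = ReversalReport()
    for day, rec in recovery_records_by_day.items():
        sig = rec[rec["significant"]]
        down = set(sig.loc[sig["meth_diff"] < 0, "site_id"])
        up = set(sig.loc[sig["meth_diff"] > 0, "site_id"])
        rh = hyper & down
        rl = hypo & up
        report.reversed_hyper[day] = rh
        report.reversed_hypo[day] = rl
        report.genes_hyper[day] = {gene_of[s] for s in rh}
        report.genes_hypo[day] = {gene_of[s] for s in rl}
    return report


def pathway_meth_density(
    sig_sites: pd.DataFrame,
    geneset_db: GeneSetDB,
    gene_universe: set[str],
) -> tuple[dict[str, float], list[str]]:
    """Significant sites per detected gene, per pathway.

    density(P) = #{significant sites on genes of P} / |P ∩ universe| where
    the universe is the set of genes detected in the methylation table.
    Pathways with no detected genes are skipped and returned second.
    """
    sites_per_gene = sig_sites.groupby("gene_id")["site_id"].nunique()
    densities: dict[str, float] = {}
    skipped: list[str] = []
    for name, genes in geneset_db.items():
        detected = genes & gene_universe
        if not detected:
            skipped.append(name)
            logger.info("pathway_meth_density: %s has no detected genes", name)
            continue
        n_sites = int(sites_per_gene.reindex(sorted(detected)).fillna(0).sum())
        densities[name] = n_sites / len(detected)
    return densities, skipped


def density_expression_correlation(
    densities: dict[str, float],
    coreg_scores: dict[str, float],
) -> dict[str, float]:
    """Pearson and Spearman correlation of methylation density against
    expression co-regulation score, over pathways present in both."""
    shared = sorted(set(densities) & set(coreg_scores))
    if len(shared) < 3:
        raise FormatError(
            f"need >=3 shared pathways for a correlation, got {len(shared)}"
        )
    x = np.array([densities[p] for p in shared], dtype=float)
    y = np.array([coreg_scores[p] for p in shared], dtype=float)
    out: dict[str, float] = {"n_pathways": len(shared)}
    if x.std() == 0 or y.std() == 0:
        logger.warning(
            "density_expression_correlation: degenerate variance; "
            "coefficients undefined"
        )
        out.update(pearson_r=np.nan, pearson_p=np.nan,
                   spearman_rho=np.nan, spearman_p=np.nan)
        return out
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    out.update(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
    )
    return out


def deg_meth_overlap(
    sig_meth_genes: set[str], deg_genes: set[str]
) -> dict[str, object]:
    """Intersection of differentially methylated and differentially
    expressed gene sets, with each side's exclusive remainder."""
    overlap = set(sig_meth_genes) & set(deg_genes)
    return {
        "overlap": overlap,
        "only_meth": set(sig_meth_genes) - overlap,
        "only_deg": set(deg_genes) - overlap,
        "n_overlap": len(overlap),
        "n_meth": len(set(sig_meth_genes)),
        "n_deg": len(set(deg_genes)),
    }
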