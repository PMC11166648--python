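"""Synthetic study generator with known ground truth.

The real mission profiled four crew members' whole blood at seven draws
(days -92, -44, -3 before launch, +1 after return, +45, +82, +194 in
recovery). The generators here emit study-shaped inputs — count matrices,
methylation site tables, transcript catalogs, sample sheets — around that
design, with planted effects recorded in a :class:`SimTruth` so every
downstream stage can be tested for parameter recovery without the mission's
raw sequencing data.

What is emulated, and how:

* **Counts** are negative-binomial per gene and sample, with a log-normal
  baseline across genes, a Normal(0, 0.2 log2-units) subject random effect
  (crew members differ), and additive log2-scale pathway effects: a
  *disrupted* pathway shifts its member genes only at the return draw, while
  a *trending* pathway follows a linear pre-flight slope that continues
  through return and then decays linearly back to baseline by the last
  recovery draw.
* **Dual quantifiers** are caricatured by their one real disagreement mode:
  within a homologous gene group, quantifier A concentrates the group's read
  total on one member (primary-mapping behavior) while quantifier B splits
  it fractionally (multi-mapping-aware behavior); group totals are conserved
  exactly, and all other genes agree up to small multiplicative noise.
* **Methylation** sites draw coverage from a negative binomial and modified
  reads from a binomial whose fraction is Beta-distributed across sites,
  spikes by a planted delta at the return draw for true effect sites, and —
  for *reversal* sites — relaxes back to baseline at the recovery draws.
  True sites carry DRACH 5-mers; a configurable fraction of null sites
  carry non-DRACH decoy 5-mers.
* **Catalogs** contain shared transcripts present everywhere up to random
  dropout, plus planted timepoint-unique transcripts present in every
  subject at their focal draw and absent everywhere else.

Every generator is a pure function of its parameters and seed.

Not emulated: raw signal, read sequences, alignment artifacts, coverage
biases along transcripts, or any correlation between expression level and
methylation — conclusions about those belong to real data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .denovo import TranscriptCatalog
from .io import (
    TIMEPOINT_DAYS,
    CountMatrix,
    FormatError,
    GeneSetDB,
    SampleMeta,
)
from .methylation import MethSiteTable, drach_check

__all__ = [
    "MissionDesign",
    "SimTruth",
    "simulate_counts",
    "simulate_dual_quantifier",
    "simulate_methylation",
    "simulate_catalog",
    "plan_methylation_effects",
    "random_geneset_db",
]


@dataclass(frozen=True)
class MissionDesign:
    """Subjects x timepoints grid defining the study's samples."""

    subjects: tuple[str, ...] = ("C001", "C002", "C003", "C004")
    timepoint_labels: tuple[str, ...] = tuple(TIMEPOINT_DAYS)
    label_days: tuple[tuple[str, int], ...] = tuple(TIMEPOINT_DAYS.items())

    @property
    def days(self) -> dict[str, int]:
        return dict(self.label_days)

    def sample_id(self, subject: str, label: str) -> str:
        return f"{subject}_{label}"

    def sample_meta(
        self, read_lengths: dict[str, float] | None = None,
        default_read_length: float = 800.0,
    ) -> list[SampleMeta]:
        """One sample per (subject, timepoint); ``read_lengths`` overrides
        the average read length QC field for named sample ids."""
        metas = []
        for subj in self.subjects:
            for label in self.timepoint_labels:
                sid = self.sample_id(subj, label)
                arl = (read_lengths or {}).get(sid, default_read_length)
                metas.append(
                    SampleMeta.from_label(
                        sid, subj, label, avg_read_length_bp=arl,
                        label_days=self.days,
                    )
                )
        return metas

    def sample_ids(self) -> list[str]:
        return [
            self.sample_id(s, t)
            for s in self.subjects
            for t in self.timepoint_labels
        ]


@dataclass
class SimTruth:
    """Planted effect structure of one synthetic study.

    ``disrupted_pathways`` maps pathway name to its return-day shift in
    log2/z units; ``trending_pathways`` to its pre-flight slope in z units
    per day. ``true_hyper_sites`` / ``true_hypo_sites`` map site id to
    (delta in percentage points, reversal flag). ``unique_transcripts`` maps
    timepoint label to the planted unique transcript ids; ``de_genes`` maps
    gene id to its return-day log2 fold change.
    """

    disrupted_pathways: dict[str, float] = field(default_factory=dict)
    trending_pathways: dict[str, float] = field(default_factory=dict)
    true_hyper_sites: dict[str, tuple[float, bool]] = field(default_factory=dict)
    true_hypo_sites: dict[str, tuple[float, bool]] = field(default_factory=dict)
    unique_transcripts: dict[str, set[str]] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        both = set(self.disrupted_pathways) & set(self.trending_pathways)
        if both:
            raise FormatError(
                f"pathways cannot be both disrupted and trending: {sorted(both)}"
            )
        for sites in (self.true_hyper_sites, self.true_hypo_sites):
            for sid, (delta, _) in sites.items():
                if abs(delta) > 100:
                    raise FormatError(
                        f"site {sid!r}: |delta| = {abs(delta)} exceeds 100pp"
                    )


def random_geneset_db(
    n_pathways: int,
    genes_per_pathway: int = 20,
    seed: int | None = None,
    prefix: str = "PATHWAY",
) -> GeneSetDB:
    """Non-overlapping synthetic pathways over a fresh gene universe."""
    names = [f"{prefix}_{i:04d}" for i in range(n_pathways)]
    sets = {}
    for i, name in enumerate(names):
        start = i * genes_per_pathway
        sets[name] = frozenset(
            f"G{j:05d}" for j in range(start, start + genes_per_pathway)
        )
    return GeneSetDB(sets=sets, descriptions={n: "synthetic" for n in names})


def _pathway_effect_by_day(
    effects: SimTruth, design: MissionDesign
) -> dict[str, dict[int, float]]:
    """Per-pathway additive log2 effect at each mission day."""
    days = sorted(design.days.values())
    last_recovery = max(days)
    out: dict[str, dict[int, float]] = {}
    for name, shift in effects.disrupted_pathways.items():
        out[name] = {d: (shift if d == 1 else 0.0) for d in days}
    for name, slope in effects.trending_pathways.items():
        eff = {}
        for d in days:
            if d <= 1:
                # the pre-flight linear trend, continued through return
                eff[d] = slope * d
            else:
                # linear relaxation to baseline by the last recovery draw
                frac = (last_recovery - d) / (last_recovery - 1)
                eff[d] = slope * 1 * frac
        out[name] = eff
    return out


def simulate_counts(
    n_genes: int,
    geneset_db: GeneSetDB,
    mission_design: MissionDesign,
    effects: SimTruth | None = None,
    dispersion: float = 10.0,
    seed: int = 0,
    baseline_log2_mean: float = 6.0,
    baseline_log2_sd: float = 1.5,
    subject_sd: float = 0.2,
) -> tuple[CountMatrix, SimTruth]:
    """Negative-binomial gene x sample counts with planted pathway effects.

    Per gene g and sample (subject s, day t), counts ~ NB with mean
    ``2 ** (b_g + u_s + e_{g,t})`` and dispersion ``dispersion`` (variance
    mu + mu^2/dispersion): b_g is a Normal(baseline_log2_mean,
    baseline_log2_sd) gene baseline, u_s a Normal(0, subject_sd) subject
    effect, and e the pathway effect of the gene's pathway at day t (summed
    if a gene sits in several effected pathways). Genes are the gene-set
    universe padded with background genes up to ``n_genes``.
    """
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    effects = effects or SimTruth()
    for name in itertools.chain(
        effects.disrupted_pathways, effects.trending_pathways
    ):
        if name not in geneset_db:
            raise FormatError(f"effect references unknown gene set {name!r}")

    pathway_genes = sorted({g for _, gs in geneset_db.items() for g in gs})
    if len(pathway_genes) > n_genes:
        raise ValueError(
            f"n_genes={n_genes} smaller than gene-set universe "
            f"({len(pathway_genes)} genes)"
        )
    genes = pathway_genes + [
        f"BG{i:05d}" for i in range(n_genes - len(pathway_genes))
    ]
    rng = np.random.default_rng(seed)
    baseline = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    subj_eff = {
        s: rng.normal(0.0, subject_sd) for s in mission_design.subjects
    }

    eff_by_day = _pathway_effect_by_day(effects, mission_design)
    gene_day_effect = np.zeros((n_genes, len(mission_design.timepoint_labels)))
    gene_index = {g: i for i, g in enumerate(genes)}
    days = [mission_design.days[t] for t in mission_design.timepoint_labels]
    for name, eff in eff_by_day.items():
        for g in geneset_db[name]:
            gi = gene_index[g]
            for ti, d in enumerate(days):
                gene_day_effect[gi, ti] += eff[d]
    for g, lfc in effects.de_genes.items():
        if g not in gene_index:
            raise FormatError(f"de_genes references unknown gene {g!r}")
        for ti, d in enumerate(days):
            if d == 1:
                gene_day_effect[gene_index[g], ti] += lfc

    cols = {}
    for subj in mission_design.subjects:
        for ti, label in enumerate(mission_design.timepoint_labels):
            log2_mu = baseline + subj_eff[subj] + gene_day_effect[:, ti]
            mu = np.exp2(log2_mu)
            p = dispersion / (dispersion + mu)
            cols[mission_design.sample_id(subj, label)] = rng.negative_binomial(
                dispersion, p
            )
    data = pd.DataFrame(cols, index=genes, dtype=float)
    return CountMatrix(data), replace(effects)


def simulate_dual_quantifier(
    counts: CountMatrix,
    homolog_groups: list[set[str]],
    seed: int = 0,
    noise_sd: float = 0.02,
    winner_frac: float = 0.9,
) -> tuple[CountMatrix, CountMatrix]:
    """Emit two quantifier views of one count matrix.

    Outside homolog groups both views equal the input up to independent
    multiplicative log2-normal noise of SD ``noise_sd`` (zero noise makes
    them identical). Inside a group, view A concentrates each sample's group
    total on the group's dominant member (``winner_frac`` of the total, the
    remainder split evenly) while view B keeps the input's fractional split;
    both conserve the group totals exactly.
    """
    flat = [g for grp in homolog_groups for g in grp]
    if len(flat) != len(set(flat)):
        raise FormatError("homolog groups overlap")
    for grp in homolog_groups:
        if len(grp) < 2:
            raise FormatError(f"homolog group {sorted(grp)} has size < 2")
        missing = grp - set(counts.gene_ids)
        if missing:
            raise FormatError(f"homolog genes not in matrix: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    base = counts.data

    def noisy() -> pd.DataFrame:
        if noise_sd == 0:
            return base.copy()
        return base * np.exp2(rng.normal(0.0, noise_sd, size=base.shape))

    a, b = noisy(), noisy()
    for grp in homolog_groups:
        members = sorted(grp)
        block = base.loc[members]
        totals = block.sum(axis=0)
        winner = block.sum(axis=1).idxmax()
        others = [m for m in members if m != winner]
        # minority shares are floored to whole reads so that the winner's
        # remainder makes the group total exact under any summation order
        share = np.floor(totals * (1 - winner_frac) / len(others))
        assigned = pd.DataFrame(
            {s: [share[s]] * len(others) for s in base.columns}, index=others
        )
        a.loc[others] = assigned
        a.loc[winner] = totals - assigned.sum(axis=0)
        b.loc[members] = block
    return CountMatrix(a), CountMatrix(b)


#: All 18 DRACH 5-mers over the DNA alphabet (T standing for U).
DRACH_KMERS = tuple(
    "".join(k)
    for k in itertools.product("AGT", "AG", "A", "C", "ACT")
)


def plan_methylation_effects(
    n_hyper: int,
    n_hypo: int,
    delta: float = 30.0,
    reversal_frac: float = 0.5,
) -> SimTruth:
    """A SimTruth naming the first ``n_hyper + n_hypo`` generated site ids.

    Site ids of :func:`simulate_methylation` are deterministic ("S00000",
    "S00001", ...), so effects can be planned without generating first. The
    first ``reversal_frac`` share of each direction's sites carry the
    reversal flag (they relax to baseline in recovery).
    """
    def plan(start: int, n: int, signed_delta: float):
        n_rev = int(round(n * reversal_frac))
        return {
            f"S{start + i:05d}": (signed_delta, i < n_rev) for i in range(n)
        }

    return SimTruth(
        true_hyper_sites=plan(0, n_hyper, abs(delta)),
        true_hypo_sites=plan(n_hyper, n_hypo, -abs(delta)),
    )


def simulate_methylation(
    n_sites: int,
    mission_design: MissionDesign,
    coverage_mean: float = 50.0,
    effects: SimTruth | None = None,
    seed: int = 0,
    coverage_dispersion: float = 20.0,
    baseline_beta: tuple[float, float] = (2.0, 8.0),
    nondrach_decoy_frac: float = 0.3,
    gene_pool: list[str] | None = None,
) -> tuple[MethSiteTable, SimTruth]:
    """Site x sample (coverage, modified-read) table with a return-day spike.

    Coverage is NB(coverage_mean); modified reads are Binomial(coverage, pi)
    with a Beta-distributed per-site baseline pi. True effect sites shift pi
    by delta/100 at the return draw; non-reversal sites keep the shift
    through recovery, reversal sites return to baseline from day +45 on.
    pi is clipped to [0, 1] with a warning naming any site whose planted
    delta overflows. True sites carry DRACH 5-mers; ``nondrach_decoy_frac``
    of null sites carry non-DRACH decoys. Hypomethylation deltas need room
    to drop, so effect-site baselines are re-centered to keep pi in range
    where possible.
    """
    if coverage_mean < 1:
        raise ValueError(f"coverage_mean must be >= 1, got {coverage_mean}")
    effects = effects or SimTruth()
    site_ids = [f"S{i:05d}" for i in range(n_sites)]
    known = set(site_ids)
    planted = {**effects.true_hyper_sites, **effects.true_hypo_sites}
    unknown = set(planted) - known
    if unknown:
        raise FormatError(
            f"effect site ids outside the generated range: {sorted(unknown)[:5]}"
        )

    rng = np.random.default_rng(seed)
    a, b = baseline_beta
    base_pi = rng.beta(a, b, size=n_sites)
    # give planted effects headroom so the shifted fraction stays in (0, 1)
    for i, sid in enumerate(site_ids):
        if sid in planted:
            delta = planted[sid][0] / 100.0
            lo, hi = (0.05, 0.95 - delta) if delta > 0 else (0.05 - delta, 0.95)
            if lo > hi:
                warnings.warn(
                    f"site {sid}: delta {planted[sid][0]}pp cannot fit in "
                    "[0,1]; fraction will be clipped",
                    stacklevel=2,
                )
            else:
                base_pi[i] = lo + base_pi[i] * (hi - lo)

    nondrach = sorted(
        set("".join(k) for k in itertools.product("ACGT", repeat=5))
        - set(DRACH_KMERS)
    )
    kmers = []
    for sid in site_ids:
        if sid in planted or rng.random() >= nondrach_decoy_frac:
            kmers.append(DRACH_KMERS[rng.integers(len(DRACH_KMERS))])
        else:
            kmers.append(nondrach[rng.integers(len(nondrach))])

    if gene_pool is None:
        gene_pool = [f"MG{i:04d}" for i in range(max(1, n_sites // 5))]
    gene_ids = [gene_pool[rng.integers(len(gene_pool))] for _ in site_ids]
    sites = pd.DataFrame(
        {
            "transcript_id": [f"{g}.t1" for g in gene_ids],
            "gene_id": gene_ids,
            "position": rng.integers(0, 2000, size=n_sites),
            "kmer": kmers,
            "region": rng.choice(["exon", "UTR"], size=n_sites, p=[0.7, 0.3]),
        },
        index=pd.Index(site_ids, name="site_id"),
    )

    days = mission_design.days
    cov_cols, mod_cols = {}, {}
    delta_arr = np.array(
        [planted.get(sid, (0.0, False))[0] / 100.0 for sid in site_ids]
    )
    reversal = np.array(
        [planted.get(sid, (0.0, False))[1] for sid in site_ids]
    )
    p_cov = coverage_dispersion / (coverage_dispersion + coverage_mean)
    for subj in mission_design.subjects:
        for label in mission_design.timepoint_labels:
            d = days[label]
            if d < 0:
                pi = base_pi
            elif d == 1:
                pi = base_pi + delta_arr
            else:
                pi = base_pi + np.where(reversal, 0.0, delta_arr)
            pi = np.clip(pi, 0.0, 1.0)
            cov = rng.negative_binomial(coverage_dispersion, p_cov, size=n_sites)
            mod = rng.binomial(cov, pi)
            sid = mission_design.sample_id(subj, label)
            cov_cols[sid] = cov
            mod_cols[sid] = mod
    table = MethSiteTable(
        sites=sites,
        coverage=pd.DataFrame(cov_cols, index=sites.index),
        mod=pd.DataFrame(mod_cols, index=sites.index),
    )
    assert all(drach_check(k) for sid, k in zip(site_ids, kmers) if sid in planted)
    return table, replace(effects)


def simulate_catalog(
    mission_design: MissionDesign,
    n_shared: int = 50,
    unique_spec: dict[str, int] | None = None,
    class_code_mix: dict[str, float] | None = None,
    dropout_rate: float = 0.05,
    seed: int = 0,
) -> tuple[TranscriptCatalog, SimTruth]:
    """Transcript catalog with shared and planted timepoint-unique transcripts.

    Shared transcripts are present in every sample except for independent
    dropout at ``dropout_rate``. Each planted unique transcript is present
    in *all* subjects at its focal timepoint and absent from every other
    sample, so it is recoverable by the strict consensus/absence rule in any
    window containing its timepoint.
    """
    unique_spec = unique_spec or {}
    unknown = set(unique_spec) - set(mission_design.timepoint_labels)
    if unknown:
        raise FormatError(f"unique_spec names unknown timepoints: {sorted(unknown)}")
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError(f"dropout_rate must be in [0,1], got {dropout_rate}")
    mix = class_code_mix or {"=": 0.2, "c": 0.2, "j": 0.2, "u": 0.4}
    codes, probs = zip(*sorted(mix.items()))
    if abs(sum(probs) - 1.0) > 1e-9:
        raise FormatError("class_code_mix probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    samples = mission_design.sample_ids()
    sample_map = {
        mission_design.sample_id(s, t): (s, t)
        for s in mission_design.subjects
        for t in mission_design.timepoint_labels
    }

    tids, rows, code_list = [], [], []
    truth_unique: dict[str, set[str]] = {tp: set() for tp in unique_spec}
    for i in range(n_shared):
        tids.append(f"TSH{i:04d}")
        rows.append(rng.random(len(samples)) >= dropout_rate)
        code_list.append(codes[rng.choice(len(codes), p=probs)])
    for tp, n in unique_spec.items():
        for i in range(n):
            tid = f"TU_{tp}_{i:02d}"
            tids.append(tid)
            rows.append(np.array([sample_map[s][1] == tp for s in samples]))
            code_list.append(codes[rng.choice(len(codes), p=probs)])
            truth_unique[tp].add(tid)

    info = pd.DataFrame(
        {
            "locus_id": [f"LOC{i:04d}" for i in range(len(tids))],
            "ref_match": [None if c == "u" else f"REF{i:04d}"
                          for i, c in enumerate(code_list)],
            "class_code": code_list,
        },
        index=pd.Index(tids, name="transcript_id"),
    )
    presence = pd.DataFrame(np.array(rows), index=info.index, columns=samples)
    catalog = TranscriptCatalog(info=info, presence=presence, sample_map=sample_map)
    return catalog, SimTruth(unique_transcripts=truth_unique)
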