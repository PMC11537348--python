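"""Genotype-likelihood re-identification of individuals from leaked host reads.

Residual human reads in putatively microbial sequencing data cover SNP sites
at very low depth.  Given per-site ref/alt read counts (n_i, k_i with k_i
reads supporting the reference allele), a candidate genotype g in {0,1,2}
(alt-allele dosage), and a per-base error probability ε, the site likelihood
is

    L(g, n, k) = (1/2^n) * [(2-g)ε + g(1-ε)]^(n-k) * [gε + (2-g)(1-ε)]^k

and the likelihood score of a genotype sample is LS = Σ_i ln L(g_i, n_i, k_i)
over independent SNP sites.  The population background follows Hardy-Weinberg
genotype frequencies (1-p)^2, 2p(1-p), p^2 from the alt allele frequency p:

    E(LS_pop) = Σ_i Σ_g P(g, p_i) ln L(g, n_i, k_i)
    V(LS_pop) = Σ_i Σ_g P(g, p_i) [ln L(g, n_i, k_i) - E(LS_i)]^2

The standardized score z = (LS - E)/sqrt(V) is converted to an upper-tail
normal P-value; a genotype matches a metagenome when its P-value beats a
Bonferroni threshold (pairwise: alpha / (M_meta * M_geno); per metagenome:
alpha / M_meta).  Sites are first reduced to an approximately independent
set by greedy sliding-window LD pruning on genotype-dosage correlation
(window 100 sites, step 30, r^2 > 0.1 drops the later site).

A synthetic cohort generator draws genotypes under HWE, sparse Poisson site
coverage and binomially sampled allele-consistent reads, and an attrition
operator thins reads to model the effect of host filtration on
re-identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypePanel",
    "AlleleFrequencyTable",
    "ReidConfig",
    "ReidResult",
    "site_log_likelihood",
    "site_likelihood",
    "likelihood_score",
    "hwe_probs",
    "expected_score",
    "variance_score",
    "standardized_pvalue",
    "ld_prune",
    "bonferroni_thresholds",
    "reidentify",
    "synthesize_cohort",
    "attrition_experiment",
]

MISSING = -1

#: Pileup tables are DataFrames with columns site_id, n, k (k = reads
#: supporting the reference allele); rows with n = 0 are excluded.
PILEUP_COLUMNS = ("site_id", "n", "k")


@dataclass(frozen=True)
class GenotypePanel:
    """Biallelic-SNP genotype matrix: sites x samples, dosages in {0,1,2}.

    Missing genotypes are stored as -1.
    """

    site_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    genotypes: np.ndarray  # int8, shape (n_sites, n_samples)

    def __init__(self, site_ids, sample_ids, genotypes):
        genotypes = np.asarray(genotypes, dtype=np.int8)
        site_ids = tuple(str(s) for s in site_ids)
        sample_ids = tuple(str(s) for s in sample_ids)
        if genotypes.shape != (len(site_ids), len(sample_ids)):
            raise ValueError("genotype matrix shape does not match site/sample ids")
        valid = np.isin(genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotypes must be 0, 1, 2 or -1 (missing)")
        object.__setattr__(self, "site_ids", site_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "genotypes", genotypes)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_sites(self, site_ids) -> "GenotypePanel":
        index = {s: i for i, s in enumerate(self.site_ids)}
        rows = [index[s] for s in site_ids]
        return GenotypePanel(tuple(site_ids), self.sample_ids, self.genotypes[rows])


#: site_id -> alternative allele frequency in [0, 1]
AlleleFrequencyTable = pd.Series


@dataclass(frozen=True)
class ReidConfig:
    epsilon: float = 1e-6
    prune_window: int = 100
    prune_step: int = 30
    prune_r2: float = 0.1
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")


@dataclass
class ReidResult:
    """All (metagenome, genotype) scores plus the Bonferroni match thresholds."""

    table: pd.DataFrame
    pairwise_threshold: float
    per_metagenome_threshold: float
    insufficient: list = field(default_factory=list)


def _bracket_logs(g: np.ndarray, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(g, dtype=float)
    alt_term = (2 - g) * epsilon + g * (1 - epsilon)  # per-read alt probability x2
    ref_term = g * epsilon + (2 - g) * (1 - epsilon)  # per-read ref probability x2
    return np.log(alt_term), np.log(ref_term)


def site_log_likelihood(g, n, k, epsilon: float = 1e-6):
    """ln L(g, n, k) for genotype dosage g in {0,1,2}; vectorized."""
    g_arr = np.asarray(g)
    if not np.isin(g_arr, (0, 1, 2)).all():
        raise ValueError("genotype dosage must be 0, 1 or 2")
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if (k < 0).any() or (k > n).any():
        raise ValueError("need 0 <= k <= n")
    log_alt, log_ref = _bracket_logs(g_arr, epsilon)
    result = -n * np.log(2.0) + (n - k) * log_alt + k * log_ref
    return result if result.ndim else float(result)


def site_likelihood(g, n, k, epsilon: float = 1e-6):
    """L(g, n, k) on the probability scale (exponentiated on demand)."""
    return np.exp(site_log_likelihood(g, n, k, epsilon))


def likelihood_score(genotypes, n, k, epsilon: float = 1e-6) -> float:
    """LS = Σ_i ln L(g_i, n_i, k_i); sites with missing genotype are skipped."""
    g = np.asarray(genotypes)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    keep = g != MISSING
    if not keep.any():
        raise ValueError("no sites with observed genotype; likelihood score undefined")
    return float(np.sum(site_log_likelihood(g[keep], n[keep], k[keep], epsilon)))


def hwe_probs(p):
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("allele frequency must be in [0, 1]")
    return (1 - p) ** 2, 2 * p * (1 - p), p**2


def _per_site_moments(p, n, k, epsilon):
    probs = np.stack(hwe_probs(p))  # (3, n_sites)
    logl = np.stack([site_log_likelihood(g, n, k, epsilon) for g in (0, 1, 2)])
    e_site = (probs * logl).sum(axis=0)
    v_site = (probs * (logl - e_site) ** 2).sum(axis=0)
    return e_site, v_site


def expected_score(freqs, n, k, epsilon: float = 1e-6) -> float:
    """E(LS_pop): HWE-weighted mean log likelihood, summed over sites."""
    e_site, _ = _per_site_moments(np.asarray(freqs, dtype=float), n, k, epsilon)
    return float(e_site.sum())


def variance_score(freqs, n, k, epsilon: float = 1e-6) -> float:
    """V(LS_pop): per-site HWE variances summed under site independence."""
    _, v_site = _per_site_moments(np.asarray(freqs, dtype=float), n, k, epsilon)
    return float(v_site.sum())


def standardized_pvalue(ls: float, e: float, v: float) -> tuple[float, float]:
    """Standardize LS against the population background; upper-tail P-value."""
    if v <= 0:
        raise ValueError("population variance must be positive")
    z = (ls - e) / np.sqrt(v)
    return float(z), float(stats.norm.sf(z))


def ld_prune(
    panel: GenotypePanel,
    window: int = 100,
    step: int = 30,
    r2_max: float = 0.1,
) -> list[str]:
    """Greedy sliding-window LD pruning on genotype-dosage correlation.

    Within each window, site pairs are scanned in index order and the
    later site of any pair with squared Pearson correlation > ``r2_max``
    is dropped.  Monomorphic sites (constant dosage column) are excluded
    up front.  Deterministic; requires >= 2 samples.
    """
    if panel.n_samples < 2:
        raise ValueError("LD pruning requires at least 2 samples")
    if panel.n_sites == 0:
        return []
    geno = np.where(panel.genotypes == MISSING, np.nan, panel.genotypes).astype(float)
    polymorphic = np.nanstd(geno, axis=1) > 0
    candidates = [i for i in range(panel.n_sites) if polymorphic[i]]
    dropped: set[int] = set()
    for w_start in range(0, max(len(candidates) - 1, 1), step):
        idx = [i for i in candidates[w_start : w_start + window] if i not in dropped]
        if len(idx) < 2:
            continue
        block = geno[idx]
        block = np.where(np.isnan(block), np.nanmean(block, axis=1, keepdims=True), block)
        corr = np.corrcoef(block)
        for a in range(len(idx)):
            if idx[a] in dropped:
                continue
            for b in range(a + 1, len(idx)):
                if idx[b] in dropped:
                    continue
                if corr[a, b] ** 2 > r2_max:
                    dropped.add(idx[b])
    return [panel.site_ids[i] for i in candidates if i not in dropped]


def bonferroni_thresholds(alpha: float, m_meta: int, m_geno: int) -> tuple[float, float]:
    """(pairwise, per-metagenome) Bonferroni significance thresholds."""
    if m_meta < 1 or m_geno < 1:
        raise ValueError("sample counts must be positive")
    return alpha / (m_meta * m_geno), alpha / m_meta


def _clean_pileup(pileup: pd.DataFrame) -> pd.DataFrame:
    missing = set(PILEUP_COLUMNS) - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup table missing columns {sorted(missing)}")
    out = pileup[pileup["n"] >= 1].copy()
    if (out["k"] < 0).any() or (out["k"] > out["n"]).any():
        raise ValueError("pileup requires 0 <= k <= n")
    return out


def reidentify(
    panel: GenotypePanel,
    pileup_sets: Mapping[str, pd.DataFrame],
    freqs: AlleleFrequencyTable,
    config: ReidConfig = ReidConfig(),
) -> ReidResult:
    """Score every (metagenome, genotype) pair and call Bonferroni matches.

    Per metagenome: restrict to its covered (n >= 1) sites that are in the
    panel with non-degenerate allele frequency, LD-prune that list, then
    compute LS, E, V, z and the upper-tail P-value for every genotype
    sample.  Metagenomes with no usable site are flagged insufficient and
    excluded from the result table (they still count toward the Bonferroni
    denominators).
    """
    pairwise_thr, per_meta_thr = bonferroni_thresholds(
        config.alpha, len(pileup_sets), panel.n_samples
    )
    site_index = {s: i for i, s in enumerate(panel.site_ids)}
    rows = []
    insufficient = []
    for meta_id, pileup in pileup_sets.items():
        pileup = _clean_pileup(pileup)
        usable = [
            s
            for s in pileup["site_id"]
            if s in site_index and s in freqs.index and 0 < freqs[s] < 1
        ]
        if not usable:
            insufficient.append(meta_id)
            continue
        sub = panel.subset_sites(usable)
        kept = ld_prune(sub, config.prune_window, config.prune_step, config.prune_r2)
        if not kept:
            insufficient.append(meta_id)
            continue
        sub = sub.subset_sites(kept)
        counts = pileup.set_index("site_id").loc[list(kept)]
        n = counts["n"].to_numpy(dtype=float)
        k = counts["k"].to_numpy(dtype=float)
        p = freqs[list(kept)].to_numpy(dtype=float)
        e_site, v_site = _per_site_moments(p, n, k, config.epsilon)
        logl = np.stack(
            [site_log_likelihood(g, n, k, config.epsilon) for g in (0, 1, 2)]
        )  # (3, N)
        geno = sub.genotypes  # (N, n_samples)
        for j, sample_id in enumerate(panel.sample_ids):
            observed = geno[:, j] != MISSING
            if not observed.any():
                continue
            ls = float(logl[geno[observed, j], np.flatnonzero(observed)].sum())
            e = float(e_site[observed].sum())
            v = float(v_site[observed].sum())
            z, pval = standardized_pvalue(ls, e, v)
            rows.append(
                {
                    "metagenome_id": meta_id,
                    "genotype_id": sample_id,
                    "n_sites": int(observed.sum()),
                    "LS": ls,
                    "E": e,
                    "V": v,
                    "z": z,
                    "p_value": pval,
                    "match_pairwise": pval < pairwise_thr,
                    "match_per_metagenome": pval < per_meta_thr,
                }
            )
    return ReidResult(
        table=pd.DataFrame(rows),
        pairwise_threshold=pairwise_thr,
        per_metagenome_threshold=per_meta_thr,
        insufficient=insufficient,
    )


def synthesize_cohort(
    n_samples: int,
    n_sites: int,
    mean_depth: float,
    epsilon: float = 1e-6,
    seed: int = 0,
    freq_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
):
    """Generate a matched genotype panel + sparse metagenome pileups.

    Allele frequencies default to uniform on [0.05, 0.95]; genotypes are
    drawn per HWE independently across sites; each metagenome (one per
    donor) covers site i with depth n_i ~ Poisson(mean_depth) — sparse when
    mean_depth < 1, emulating host-read scarcity in fecal data — and its
    reference-supporting count k_i ~ Binomial(n_i, q) with q = 1-ε, 0.5, ε
    for donor dosage 0, 1, 2.

    Returns (panel, freqs, pileup_sets, donors) where donors maps
    metagenome id -> donor sample id.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    if freq_sampler is None:
        p = rng.uniform(0.05, 0.95, size=n_sites)
    else:
        p = np.asarray(freq_sampler(rng, n_sites), dtype=float)
    p0, p1, _ = hwe_probs(p)
    u = rng.random((n_sites, n_samples))
    genotypes = (u > p0[:, None]).astype(np.int8) + (u > (p0 + p1)[:, None]).astype(np.int8)
    site_ids = [f"site{i}" for i in range(n_sites)]
    sample_ids = [f"sample{j}" for j in range(n_samples)]
    panel = GenotypePanel(site_ids, sample_ids, genotypes)
    freqs = pd.Series(p, index=site_ids)
    ref_prob = np.array([1 - epsilon, 0.5, epsilon])
    pileup_sets: dict[str, pd.DataFrame] = {}
    donors: dict[str, str] = {}
    for j, sample_id in enumerate(sample_ids):
        meta_id = f"meta{j}"
        n = rng.poisson(mean_depth, size=n_sites)
        covered = np.flatnonzero(n)
        k = rng.binomial(n[covered], ref_prob[genotypes[covered, j]])
        pileup_sets[meta_id] = pd.DataFrame(
            {
                "site_id": [site_ids[i] for i in covered],
                "n": n[covered].astype(int),
                "k": k.astype(int),
            }
        )
        donors[meta_id] = sample_id
    return panel, freqs, pileup_sets, donors


def attrition_experiment(
    pileup_sets: Mapping[str, pd.DataFrame], retention_fraction: float, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Thin every pileup read independently with the given retention probability.

    Models host filtration removing leaked human reads; n and k are
    recomputed and zero-coverage sites dropped.
    """
    if not 0 <= retention_fraction <= 1:
        raise ValueError("retention_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for meta_id, pileup in pileup_sets.items():
        pileup = _clean_pileup(pileup)
        k = pileup["k"].to_numpy(dtype=int)
        alt = pileup["n"].to_numpy(dtype=int) - k
        k_new = rng.binomial(k, retention_fraction)
        alt_new = rng.binomial(alt, retention_fraction)
        n_new = k_new + alt_new
        keep = n_new >= 1
        out[meta_id] = pd.DataFrame(
            {
                "site_id": pileup["site_id"].to_numpy()[keep],
                "n": n_new[keep],
                "k": k_new[keep],
            }
        )
    return out
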