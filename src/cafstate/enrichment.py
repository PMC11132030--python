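"""Preranked GSEA, ssGSEA and composite CAF-subset scores.

The enrichment score (ES) is the extremum of the weighted Kolmogorov-
Smirnov running sum over a ranked gene list: genes in the set increment
the sum by |score|^w (normalised so the hit increments total 1) and genes
outside decrement it by 1/(N - |S|). NES normalises ES by the mean |ES| of
same-sign gene-label permutations; the permutation p-value carries an
add-one correction so p is never zero.

A CAF subset score for one expression profile is NES(up-signature) minus
NES(down-signature), so a profile only scores high when it both gains the
subset's up-regulated genes and loses its down-regulated ones. The
per-patient variant uses ssGSEA (sum of weighted hit-vs-miss ECDF
differences over within-sample expression ranks) in place of NES.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SubsetSignature",
    "EnrichmentResult",
    "CAFSubsetScore",
    "rank_genes",
    "build_signatures",
    "gsea_es",
    "gsea_preranked",
    "caf_subset_score",
    "ssgsea_score",
    "patient_subset_score",
    "tf_concordance",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class SubsetSignature:
    """Up- and down-regulated gene sets characterising one CAF subset."""

    subset: str
    up: frozenset[str]
    down: frozenset[str]
    lfc_threshold: float = 0.25
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        up, down = frozenset(self.up), frozenset(self.down)
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)
        if up & down:
            raise ValueError(f"up and down sets overlap: {sorted(up & down)}")


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int | None = None


@dataclass(frozen=True)
class CAFSubsetScore:
    subset: str
    nes_up: float
    nes_down: float

    @property
    def score(self) -> float:
        return self.nes_up - self.nes_down


def rank_genes(scores: pd.Series) -> pd.Series:
    """Sort a gene->score series descending; ties broken by gene name."""
    s = scores.astype(float)
    if s.index.has_duplicates:
        raise ValueError("ranked list contains duplicate genes")
    if not np.all(np.isfinite(s.to_numpy())):
        raise ValueError("ranking scores must be finite")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def _normalize_cpm(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts cannot be normalised")
    return counts / totals * scale


def build_signatures(
    counts: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    lfc_threshold: float = 0.25,
    p_threshold: float = 0.05,
) -> dict[str, SubsetSignature]:
    """Differential-expression signatures, one per subset (subset vs rest).

    Per gene: two-sided Wilcoxon rank-sum on library-size-normalised
    expression with BH adjustment; up set = log2FC > threshold and
    adjusted p < cutoff, down set symmetric. Inequalities are strict.
    """
    labels = pd.Series(np.asarray(labels), index=counts.columns)
    subsets = sorted(labels.unique())
    if len(subsets) < 2:
        raise ValueError("need at least two subsets")
    norm = _normalize_cpm(counts).to_numpy(dtype=float)
    genes = counts.index.to_numpy()

    signatures: dict[str, SubsetSignature] = {}
    for subset in subsets:
        in_grp = (labels == subset).to_numpy()
        if in_grp.sum() < 2 or (~in_grp).sum() < 2:
            raise ValueError(f"subset {subset!r} needs >=2 cells on both sides")
        x, y = norm[:, in_grp], norm[:, ~in_grp]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant genes yield exact-tie warnings
            res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
        padj = multipletests(res.pvalue, method="fdr_bh")[1]
        lfc = np.log2((x.mean(axis=1) + 1.0) / (y.mean(axis=1) + 1.0))
        up = frozenset(genes[(lfc > lfc_threshold) & (padj < p_threshold)])
        down = frozenset(genes[(lfc < -lfc_threshold) & (padj < p_threshold)])
        signatures[subset] = SubsetSignature(
            subset=subset, up=up, down=down,
            lfc_threshold=lfc_threshold, p_threshold=p_threshold,
        )
    return signatures


def _hit_miss_increments(
    scores: np.ndarray, hits: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Signed per-position running-sum increments for one ranked list."""
    n = scores.size
    n_hits = int(hits.sum())
    inc = np.empty(n, dtype=float)
    w = np.abs(scores[hits]) ** weight_exponent
    total = w.sum()
    if total == 0:  # all hit scores zero -> equal weights
        w = np.ones(n_hits)
        total = float(n_hits)
    inc[hits] = w / total
    if n_hits < n:
        inc[~hits] = -1.0 / (n - n_hits)
    return inc


def gsea_es(
    ranked: pd.Series, gene_set: set[str], weight_exponent: float = 1.0
) -> float:
    """Enrichment score: signed extremum of the weighted KS running sum."""
    ranked = rank_genes(ranked)
    hits = ranked.index.isin(gene_set)
    if not hits.any():
        raise ValueError("gene set does not intersect the ranked list")
    inc = _hit_miss_increments(ranked.to_numpy(), hits, weight_exponent)
    running = np.cumsum(inc)
    return float(running[np.argmax(np.abs(running))])


def _permutation_es(
    scores: np.ndarray, n_hits: int, weight_exponent: float, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of ``n_perm`` random gene-label permutations of the set, vectorised."""
    n = scores.size
    # random hit positions per permutation: first n_hits of a random argsort
    hit_pos = rng.random((n_perm, n)).argsort(axis=1)[:, :n_hits]
    inc = np.full((n_perm, n), -1.0 / (n - n_hits) if n_hits < n else 0.0)
    rows = np.arange(n_perm)[:, None]
    w = np.abs(scores[hit_pos]) ** weight_exponent
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        totals[zero] = n_hits
    inc[rows, hit_pos] = w / totals
    running = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def gsea_preranked(
    ranked: pd.Series,
    gene_set: set[str],
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Preranked GSEA with a gene-label permutation null.

    NES = ES / mean(|permutation ES| of the same sign); p-value is the
    add-one-corrected fraction of same-sign permutation ES at least as
    extreme as the observed ES.
    """
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives unstable NES/p", stacklevel=2)
    ranked = rank_genes(ranked)
    es = gsea_es(ranked, gene_set, weight_exponent)
    n_hits = int(ranked.index.isin(gene_set).sum())
    rng = np.random.default_rng(seed)
    perm = _permutation_es(ranked.to_numpy(), n_hits, weight_exponent, n_perm, rng)

    same_sign = perm * np.sign(es) > 0 if es != 0 else np.ones_like(perm, dtype=bool)
    n_same = int(same_sign.sum())
    if n_same == 0:
        warnings.warn("no same-sign permutation ES: NES undefined", stacklevel=2)
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(perm[same_sign]))
        p = (np.sum(np.abs(perm[same_sign]) >= abs(es)) + 1.0) / (n_same + 1.0)
    return EnrichmentResult(es=es, nes=float(nes), p_value=float(p),
                            n_permutations=n_perm, seed=seed)


def caf_subset_score(
    ranked: pd.Series,
    signature: SubsetSignature,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> CAFSubsetScore:
    """NES of the up-signature minus NES of the down-signature.

    Positive when the profile resembles the subset in both directions:
    its up-regulated genes sit high in the ranking and its down-regulated
    genes sit low.
    """
    if not signature.up or not signature.down:
        raise ValueError("both up and down sets must be non-empty for scoring")
    up = gsea_preranked(ranked, set(signature.up), weight_exponent, n_perm, seed)
    down = gsea_preranked(ranked, set(signature.down), weight_exponent, n_perm,
                          None if seed is None else seed + 1)
    return CAFSubsetScore(subset=signature.subset, nes_up=up.nes, nes_down=down.nes)


def ssgsea_score(
    expression: pd.Series, gene_set: set[str], alpha: float = 0.25
) -> float:
    """Single-sample GSEA score.

    Genes are ranked by within-sample expression (descending); the score is
    the sum over all rank positions of the difference between the
    weighted hit ECDF (weights = rank^alpha, top gene has rank N) and the
    unweighted miss ECDF. With an all-gene set the miss ECDF has no mass
    and contributes 0 by definition.
    """
    ranked = rank_genes(expression)
    hits = ranked.index.isin(gene_set)
    if not hits.any():
        raise ValueError("gene set absent from the expression profile")
    n = len(ranked)
    rank_weight = np.arange(n, 0, -1, dtype=float) ** alpha
    hit_w = np.where(hits, rank_weight, 0.0)
    ecdf_hit = np.cumsum(hit_w) / hit_w.sum()
    n_miss = n - int(hits.sum())
    if n_miss == 0:
        ecdf_miss = np.zeros(n)
    else:
        ecdf_miss = np.cumsum(~hits) / n_miss
    return float(np.sum(ecdf_hit - ecdf_miss))


def patient_subset_score(
    expression: pd.Series, signature: SubsetSignature, alpha: float = 0.25
) -> float:
    """Per-sample CAF subset score: ssGSEA(up) - ssGSEA(down)."""
    if not signature.up or not signature.down:
        raise ValueError("both up and down sets must be non-empty for scoring")
    return ssgsea_score(expression, set(signature.up), alpha) - ssgsea_score(
        expression, set(signature.down), alpha
    )


def tf_concordance(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    p_threshold: float = 0.05,
) -> tuple[float, dict]:
    """Percent of transcription factors with agreeing enrichment signs.

    Each profile is a table with columns ``tf`` and ``nes`` (and optionally
    ``p_value``; rows with p >= threshold are dropped). The denominator is
    the union of significant TFs across the two profiles; a TF present in
    only one profile counts as discordant. The exact definition is
    recorded in the returned metadata because upstream conventions vary.
    """
    def significant(profile: pd.DataFrame) -> pd.Series:
        df = profile.copy()
        if "p_value" in df.columns:
            df = df[df["p_value"] < p_threshold]
        return df.set_index("tf")["nes"].astype(float)

    a, b = significant(profile_a), significant(profile_b)
    union = set(a.index) | set(b.index)
    if not union:
        raise ValueError("no significant TFs in either profile")
    agree = sum(
        1
        for tf in union
        if tf in a.index and tf in b.index and np.sign(a[tf]) == np.sign(b[tf]) != 0
    )
    percent = 100.0 * agree / len(union)
    meta = {
        "definition": "sign agreement over the union of significant TFs; "
        "TFs significant in only one profile count as discordant",
        "p_threshold": p_threshold,
        "n_union": len(union),
        "n_agree": agree,
    }
    return percent, meta


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def signatures_to_gmt(signatures: dict[str, SubsetSignature], path) -> None:
    """Write subset signatures as paired <subset>_up / <subset>_down GMT sets."""
    sets = {}
    for name, sig in signatures.items():
        sets[f"{name}_up"] = set(sig.up)
        sets[f"{name}_down"] = set(sig.down)
    write_gmt(sets, path)
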