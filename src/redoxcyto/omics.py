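"""Redox-stratified comparison of protein and transcript abundance matrices.

Label-free protein intensities and 3'-count transcript tables from sorted
reduced/oxidized subpopulations (two culture ages, three replicates) are
normalized, clustered, and tested per feature for differential abundance.
Features passing both the FDR and the two-fold-change filter feed a
protein-mRNA coupling classification that flags genes whose protein and
transcript move in opposite directions between the redox states.

The differential test reports a per-feature Welch t statistic on log2
values.  By default the multiplicity correction is permutation-based:
sample labels are reassigned (exhaustively when the distinct relabelings
are few, randomly otherwise; the observed grouping and its mirror are
excluded), a variance-moderated statistic d = diff/(s0 + se) is pooled
across features and relabelings into a null, and the resulting per-feature
permutation p-values are Benjamini-Hochberg adjusted (this equals the
classical pooled E[false positives]/R estimate after the monotonicity
pass, and guarantees q >= p).  The moderation offset s0 -- the median
per-feature standard error -- keeps features with spuriously tiny
within-group variance from dominating the ranking at n = 3, where a raw t
can explode without any real effect.  Plain BH on the parametric Welch
p-values is available as an option.  The transcript-side test is the pipeline's own
substitute on log2(PPM + 1); it is not a negative-binomial count model and
is labeled accordingly in its outputs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceMatrix",
    "DiffResult",
    "CouplingTable",
    "HClusterResult",
    "median_log_normalize",
    "hcluster",
    "diff_abundance",
    "ppm_normalize",
    "diff_expression_rna",
    "coupling_classes",
    "linkage_to_newick",
]


@dataclass
class AbundanceMatrix:
    """A features-by-samples abundance matrix with its sample sheet.

    ``values`` is indexed by feature id with sample ids as columns;
    ``samples`` is indexed by sample id with ``redox`` ({reduced, oxidized}),
    ``age`` (hours) and ``replicate`` columns.  ``modality`` is ``protein``
    (log-scale intensities allowed to contain NaN for missing) or ``rna``
    (nonnegative counts or PPM).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    modality: str = "protein"

    def __post_init__(self) -> None:
        if self.modality not in ("protein", "rna"):
            raise ValueError("modality must be 'protein' or 'rna'")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet missing entries for {sorted(missing)}")
        if self.modality == "rna" and (self.values.to_numpy() < 0).any():
            raise ValueError("counts cannot be negative")
        for (redox, age), grp in self.samples.groupby(["redox", "age"]):
            if len(grp) < 2:
                warnings.warn(f"group ({redox}, {age}) has fewer than 2 replicates")

    def select(self, **criteria) -> "AbundanceMatrix":
        """Subset samples by sheet columns, e.g. ``select(age=48)``."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        keep = self.samples.index[mask]
        return AbundanceMatrix(self.values[keep], self.samples.loc[keep], self.modality)


@dataclass(frozen=True)
class DiffResult:
    """Per-feature differential-abundance statistics (oxidized vs reduced)."""

    table: pd.DataFrame  # feature-indexed: log2fc, t, p, q, significant
    contrast: str
    alpha: float
    fc_min: float
    method: str
    note: str = ""

    @property
    def significant_features(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


@dataclass(frozen=True)
class CouplingTable:
    """Per-gene protein/transcript coupling classes."""

    table: pd.DataFrame  # gene-indexed: protein_log2fc, rna_log2fc, coupling_class


@dataclass(frozen=True)
class HClusterResult:
    sample_linkage: np.ndarray
    sample_order: tuple[str, ...]
    feature_linkage: np.ndarray | None
    feature_clusters: pd.Series | None


def median_log_normalize(m: AbundanceMatrix, *, pseudo: float = 0.0) -> AbundanceMatrix:
    """Divide each row by its median, then take log2.

    Output rows have median 0 (exactly, for an odd sample count).  Rows
    whose median is nonpositive after the pseudo-offset are dropped with a
    warning.  ``pseudo`` shifts count data away from zero before the ratio.
    """
    vals = m.values.astype(float) + pseudo
    med = vals.median(axis=1)
    bad = ~(med > 0)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} rows with nonpositive median")
        vals = vals.loc[~bad]
        med = med.loc[~bad]
    out = np.log2(vals.div(med, axis=0))
    return AbundanceMatrix(out, m.samples.copy(), m.modality)


def hcluster(
    m: AbundanceMatrix,
    *,
    n_feature_clusters: int | None = None,
    cluster_features: bool = True,
) -> HClusterResult:
    """Average-linkage clustering under the centered-correlation metric.

    Distance between two profiles is ``1 - Pearson r`` (mean-centered).
    Samples are always clustered; features optionally, with flat clusters
    cut at ``n_feature_clusters``.  A zero-variance sample vector makes the
    correlation undefined and raises with the offending sample named.
    """
    vals = m.values.dropna(axis=0)
    arr = vals.to_numpy(dtype=float)
    for j, name in enumerate(vals.columns):
        if np.isclose(arr[:, j].std(), 0.0):
            raise ValueError(f"sample {name!r} has zero variance; correlation undefined")
    sample_linkage = linkage(pdist(arr.T, metric="correlation"), method="average")
    feature_linkage = None
    feature_clusters = None
    if cluster_features and len(vals) >= 2:
        keep = arr.std(axis=1) > 0
        feats = vals.index[keep]
        feature_linkage = linkage(pdist(arr[keep], metric="correlation"), method="average")
        if n_feature_clusters is not None:
            flat = fcluster(feature_linkage, t=n_feature_clusters, criterion="maxclust")
            feature_clusters = pd.Series(flat, index=feats, name="cluster")
    return HClusterResult(
        sample_linkage=sample_linkage,
        sample_order=tuple(vals.columns),
        feature_linkage=feature_linkage,
        feature_clusters=feature_clusters,
    )


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = to_tree(Z)

    def _walk(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _walk(tree, tree.dist) + ";"


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized nan-aware Welch t over feature rows; returns (t, df, lfc)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        na = np.sum(~np.isnan(a), axis=1)
        nb = np.sum(~np.isnan(b), axis=1)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df, ma - mb


def _bh_monotone_q(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _moderated_d(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    """Variance-moderated difference statistic d = (mean_a - mean_b)/(s0 + se).

    The exchangeability offset ``s0`` (a pooled scale, here the median
    per-feature standard error) keeps features with spuriously tiny
    within-group variance from dominating the permutation ranking.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        na = np.sum(~np.isnan(a), axis=1)
        nb = np.sum(~np.isnan(b), axis=1)
        diff = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
        se = np.sqrt(np.nanvar(a, axis=1, ddof=1) / na + np.nanvar(b, axis=1, ddof=1) / nb)
    return np.nan_to_num(diff / (s0 + se), nan=0.0)


def diff_abundance(
    m: AbundanceMatrix,
    age: int,
    *,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    method: str = "permutation",
    n_perm: int = 250,
    seed: int = 0,
    max_missing_per_group: int = 1,
    note: str = "",
) -> DiffResult:
    """Per-feature oxidized-vs-reduced test at one culture age.

    Welch t on log2-scale values; positive ``log2fc`` means higher in the
    oxidized cells.  With ``method="permutation"`` the per-feature p-value
    comes from the pooled null of variance-moderated |d| statistics over
    ``n_perm`` random sample relabelings (the observed grouping and its
    mirror are excluded from the draws but enter the reference set once),
    then BH-adjusted to q; ``method="bh"`` uses the parametric Welch p
    directly.  A feature is significant when ``q <= alpha`` and
    ``|log2fc| >= log2(fc_min)``.

    Features with missing values in more than ``max_missing_per_group``
    replicates of either group are excluded up front; remaining missing
    values are handled nan-aware, never imputed.
    """
    sub = m.select(age=age)
    ox_cols = sub.samples.index[sub.samples["redox"] == "oxidized"]
    red_cols = sub.samples.index[sub.samples["redox"] == "reduced"]
    if len(ox_cols) < 2 or len(red_cols) < 2:
        raise ValueError("need at least 2 replicates per redox group")

    vals = sub.values.astype(float)
    a = vals[ox_cols].to_numpy()
    b = vals[red_cols].to_numpy()
    ok = (np.isnan(a).sum(axis=1) <= max_missing_per_group) & (
        np.isnan(b).sum(axis=1) <= max_missing_per_group
    )
    features = vals.index[ok]
    a, b = a[ok], b[ok]

    t_obs, df_obs, lfc = _welch_t(a, b)
    abs_t = np.abs(np.nan_to_num(t_obs, nan=0.0))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        se_obs = np.sqrt(
            np.nanvar(a, axis=1, ddof=1) / np.sum(~np.isnan(a), axis=1)
            + np.nanvar(b, axis=1, ddof=1) / np.sum(~np.isnan(b), axis=1)
        )
    s0 = float(np.nanmedian(se_obs)) if np.isfinite(se_obs).any() else 1.0

    n_ox, n_red = len(ox_cols), len(red_cols)
    n_distinct = math.comb(n_ox + n_red, n_ox)
    used_method = method
    if method == "permutation" and n_distinct <= 2:
        warnings.warn("too few distinct relabelings to permute; falling back to BH")
        used_method = "bh"

    if used_method == "permutation":
        rng = np.random.default_rng(seed)
        # canonical column order so the null is identical under label swap
        all_cols = sorted(list(ox_cols) + list(red_cols))
        pooled = vals.loc[features, all_cols].to_numpy()
        n_tot = n_ox + n_red
        ox_positions = frozenset(i for i, c in enumerate(all_cols) if c in set(ox_cols))
        red_positions = frozenset(range(n_tot)) - ox_positions
        abs_d = np.abs(_moderated_d(a, b, s0))
        null_counts = np.zeros(a.shape[0])
        order = np.argsort(abs_d)
        sorted_abs_d = abs_d[order]

        # relabelings that reproduce the observed grouping (or its mirror)
        # are excluded: they would leak the signal into the null.  When the
        # distinct relabelings are few they are enumerated exhaustively --
        # resampling the same handful many times would only inflate the
        # denominator without adding evidence.
        def _splits():
            if n_distinct <= n_perm:
                for comb in itertools.combinations(range(n_tot), n_ox):
                    grp = frozenset(comb)
                    if grp == ox_positions or (n_ox == n_red and grp == red_positions):
                        continue
                    yield list(comb), [i for i in range(n_tot) if i not in grp]
            else:
                done = 0
                while done < n_perm:
                    idx = rng.permutation(n_tot)
                    grp = frozenset(idx[:n_ox].tolist())
                    if grp == ox_positions or (n_ox == n_red and grp == red_positions):
                        continue
                    done += 1
                    yield idx[:n_ox].tolist(), idx[n_ox:].tolist()

        total_null = 0
        for ga, gb in _splits():
            d_null = np.abs(_moderated_d(pooled[:, ga], pooled[:, gb], s0))
            # for each observed |d|, count pooled null values >= it
            counts_ge = d_null.size - np.searchsorted(np.sort(d_null), sorted_abs_d, side="left")
            null_counts[order] += counts_ge
            total_null += d_null.size
        # add-one smoothing: the observed statistic itself counts once
        p = (null_counts + 1.0) / (total_null + 1.0)
    else:
        with np.errstate(invalid="ignore"):
            p = 2.0 * t_dist.sf(abs_t, np.where(np.isfinite(df_obs), df_obs, 1.0))
        p = np.where(np.isfinite(t_obs), p, 1.0)

    q = _bh_monotone_q(p)
    significant = (q <= alpha) & (np.abs(lfc) >= np.log2(fc_min))
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t_obs,
            "p": p,
            "q": q,
            "significant": significant,
        },
        index=features,
    )
    return DiffResult(
        table=table,
        contrast=f"oxidized vs reduced @ {age} h",
        alpha=alpha,
        fc_min=fc_min,
        method=used_method,
        note=note,
    )


def ppm_normalize(counts: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample's counts to parts-per-million of its total.

    Every output column sums to exactly 1e6.  A zero-sum column cannot be
    normalized and raises.
    """
    if counts.modality != "rna":
        raise ValueError("ppm_normalize expects an rna (count) matrix")
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    out = counts.values.astype(float).div(totals, axis=1) * 1e6
    return AbundanceMatrix(out, counts.samples.copy(), "rna")


def diff_expression_rna(
    ppm: AbundanceMatrix,
    age: int,
    *,
    alpha: float = 0.05,
    fc_min: float = 2.0,
    pseudo: float = 1.0,
    **kwargs,
) -> DiffResult:
    """Transcript-side differential test on log2(PPM + pseudo).

    This is the pipeline's own substitute test (Welch t with permutation
    FDR), not a negative-binomial count model; results carry a note saying
    so.
    """
    logged = AbundanceMatrix(
        np.log2(ppm.values.astype(float) + pseudo), ppm.samples.copy(), "protein"
    )
    res = diff_abundance(
        logged,
        age,
        alpha=alpha,
        fc_min=fc_min,
        note="substitute test: Welch t on log2(PPM + offset), not a count model",
        **kwargs,
    )
    return res


_CLASS_NAMES = {
    (True, 1): "coupled-oxidized",
    (True, -1): "coupled-reduced",
    (False, 1): "uncoupled-protein-oxidized",
    (False, -1): "uncoupled-protein-reduced",
}


def coupling_classes(prot: DiffResult, rna: DiffResult) -> CouplingTable:
    """Classify protein-significant genes by transcript agreement.

    For each gene whose protein change is significant: ``coupled`` when the
    transcript log2 fold change has the same sign (named by the direction
    of the protein change: -oxidized for protein up in oxidized cells),
    ``uncoupled`` when it is opposite.  Everything else is ``ns``.  A
    transcript fold change of exactly zero counts as coupled (no opposing
    evidence).
    """
    shared = prot.table.index.intersection(rna.table.index)
    if len(shared) == 0:
        raise ValueError("no shared gene identifiers between protein and rna results")
    p_lfc = prot.table.loc[shared, "log2fc"]
    r_lfc = rna.table.loc[shared, "log2fc"]
    sig = prot.table.loc[shared, "significant"]
    classes = []
    for gene in shared:
        if not sig[gene] or p_lfc[gene] == 0:
            classes.append("ns")
            continue
        direction = 1 if p_lfc[gene] > 0 else -1
        coupled = (r_lfc[gene] * p_lfc[gene]) >= 0
        classes.append(_CLASS_NAMES[(coupled, direction)])
    table = pd.DataFrame(
        {
            "protein_log2fc": p_lfc,
            "rna_log2fc": r_lfc,
            "protein_significant": sig,
            "coupling_class": classes,
        },
        index=shared,
    )
    return CouplingTable(table=table)
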