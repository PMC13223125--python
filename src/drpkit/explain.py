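"""Model attribution and pathway over-representation.

Kernel SHAP attributes a model's scalar output for one sample to its
input features against a background distribution drawn from training
folds. For small feature counts all coalitions are enumerated, giving the
exact Shapley values under the background distribution (so the
efficiency, symmetry and null-feature axioms hold exactly); for larger
counts coalitions are sampled under the Shapley kernel weights and the
attributions solve a sum-constrained weighted least squares, so local
accuracy (base + sum of attributions = model output) is preserved.

Pathway over-representation: upper-tail hypergeometric tests of a ranked
gene list against gene sets read from GMT files, with Benjamini-Hochberg
control of the false discovery rate (significance at FDR < 0.05). The
gene universe is the set of genes represented in the feature matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class LeakageError(RuntimeError):
    """Background rows overlap the rows being explained."""


@dataclass
class Attribution:
    values: np.ndarray            # (n_samples, n_features)
    base_value: float
    feature_names: list[str]
    background_size: int
    seed: Optional[int] = None


def _shapley_kernel_weight(m: int, s: int) -> float:
    """Shapley kernel for a coalition of size s out of m features."""
    if s == 0 or s == m:
        return math.inf
    return (m - 1) / (math.comb(m, s) * s * (m - s))


def _coalition_value(
    model: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    mask: np.ndarray,
) -> float:
    """E_b f(x on mask, b off mask): mean model output over the background."""
    synth = background.copy()
    synth[:, mask] = x[mask]
    return float(np.mean(model(synth)))


def _exact_shapley(
    model, x: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    m = x.size
    values = {}
    for size in range(m + 1):
        for combo in combinations(range(m), size):
            mask = np.zeros(m, dtype=bool)
            mask[list(combo)] = True
            values[combo] = _coalition_value(model, x, background, mask)
    base = values[()]
    phi = np.zeros(m)
    fact = math.factorial
    for j in range(m):
        others = [i for i in range(m) if i != j]
        for size in range(m):
            w = fact(size) * fact(m - size - 1) / fact(m)
            for combo in combinations(others, size):
                with_j = tuple(sorted(combo + (j,)))
                phi[j] += w * (values[with_j] - values[combo])
    return phi, base


def _sampled_kernel_shap(
    model, x: np.ndarray, background: np.ndarray, rng: np.random.Generator,
    n_samples: int,
) -> tuple[np.ndarray, float]:
    m = x.size
    base = _coalition_value(model, x, background, np.zeros(m, dtype=bool))
    full = _coalition_value(model, x, background, np.ones(m, dtype=bool))
    Z = np.zeros((n_samples, m), dtype=bool)
    w = np.zeros(n_samples)
    sizes = np.arange(1, m)
    size_w = np.array([_shapley_kernel_weight(m, s) for s in sizes])
    size_p = size_w / size_w.sum()
    for i in range(n_samples):
        s = rng.choice(sizes, p=size_p)
        Z[i, rng.choice(m, size=s, replace=False)] = True
        w[i] = 1.0  # kernel weight absorbed into the size-sampling law
    y = np.array(
        [_coalition_value(model, x, background, Z[i]) for i in range(n_samples)]
    )
    # constrained WLS: min ||sqrt(W)(Z phi - (y - base))|| s.t. 1^T phi = full - base
    A = Z.astype(float)
    WA = A * w[:, None]
    G = A.T @ WA + 1e-8 * np.eye(m)
    b = WA.T @ (y - base)
    ones = np.ones(m)
    Ginv_b = np.linalg.solve(G, b)
    Ginv_1 = np.linalg.solve(G, ones)
    mu = (ones @ Ginv_b - (full - base)) / (ones @ Ginv_1)
    phi = Ginv_b - mu * Ginv_1
    return phi, base


def kernel_shap(
    model: Callable[[np.ndarray], np.ndarray],
    samples: np.ndarray,
    background: np.ndarray,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
    max_exact: int = 12,
    n_coalitions: int = 2048,
    sample_ids: Optional[Sequence] = None,
    background_ids: Optional[Sequence] = None,
) -> Attribution:
    """Kernel SHAP attributions for each sample row.

    ``model`` maps an (n, m) array to n scalar outputs. With at most
    ``max_exact`` features every coalition is enumerated (exact Shapley
    under the background distribution); otherwise coalitions are sampled
    with the given seed. Backgrounds must come from training folds only:
    when row identifiers are supplied for both sides, any overlap raises
    :class:`LeakageError`.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    m = samples.shape[1]
    if background.shape[1] != m:
        raise ValueError("background and samples disagree on feature count")
    if sample_ids is not None and background_ids is not None:
        overlap = set(sample_ids) & set(background_ids)
        if overlap:
            raise LeakageError(
                f"background rows overlap the explained samples: "
                f"{sorted(overlap)[:5]}"
            )
    rng = np.random.default_rng(seed)
    values = np.zeros_like(samples)
    base = 0.0
    for i, x in enumerate(samples):
        if m <= max_exact:
            phi, base = _exact_shapley(model, x, background)
        else:
            phi, base = _sampled_kernel_shap(model, x, background, rng, n_coalitions)
        values[i] = phi
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(m)
    ]
    return Attribution(
        values=values, base_value=base, feature_names=names,
        background_size=len(background), seed=seed,
    )


def rank_features(attribution: Attribution) -> list[tuple[str, float]]:
    """Features by descending mean |SHAP|, ties broken lexicographically."""
    if attribution.values.shape[0] < 1:
        raise ValueError("need at least one explained sample")
    mean_abs = np.abs(attribution.values).mean(axis=0)
    order = sorted(
        zip(attribution.feature_names, mean_abs), key=lambda t: (-t[1], t[0])
    )
    return [(name, float(v)) for name, v in order]


def top_k_genes(
    ranked: Sequence[tuple[str, float]],
    feature_to_gene: Mapping[str, str],
    k: int = 50,
) -> list[str]:
    """First K distinct genes in rank order; unmapped columns are skipped."""
    genes: list[str] = []
    for name, _ in ranked:
        gene = feature_to_gene.get(name)
        if gene and gene not in genes:
            genes.append(gene)
        if len(genes) == k:
            return genes
    warnings.warn(
        f"only {len(genes)} mappable genes available (requested {k})",
        stacklevel=2,
    )
    return genes


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Standard GMT: tab-separated set name, description, member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def hypergeom_enrich(
    gene_list: Sequence[str],
    gene_sets: Mapping[str, tuple[str, Sequence[str]]],
    universe: Sequence[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH control.

    For each set: p = P(X >= overlap) with X hypergeometric(universe
    size, set size within the universe, list size). Rows are sorted by
    adjusted FDR; a set is significant at FDR < ``fdr_threshold``.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    hits = set(gene_list) & universe_set
    M, N = len(universe_set), len(hits)
    rows = []
    for name, (desc, members) in gene_sets.items():
        in_universe = set(members) & universe_set
        K = len(in_universe)
        overlap = len(in_universe & hits)
        p = float(stats.hypergeom.sf(overlap - 1, M, K, N)) if K else 1.0
        rows.append(
            {
                "gene_set": name,
                "description": desc,
                "overlap": overlap,
                "set_size": K,
                "universe_size": M,
                "list_size": N,
                "p_value": min(p, 1.0),
            }
        )
    report = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    _, fdr, _, _ = multipletests(report["p_value"], method="fdr_bh")
    report["fdr"] = fdr
    report["significant"] = report["fdr"] < fdr_threshold
    return report.sort_values(["fdr", "p_value", "gene_set"]).reset_index(drop=True)


def attribution_gene_map(
    feature_names: Sequence[str], genes: Sequence[str]
) -> dict[str, str]:
    """Map omics feature columns (e.g. ``expression_G0001``) to gene symbols."""
    gene_set = set(genes)
    mapping = {}
    for name in feature_names:
        tail = name.rsplit("_", 1)[-1]
        if tail in gene_set:
            mapping[name] = tail
    return mapping
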