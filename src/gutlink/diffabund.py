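"""Per-taxon group-difference testing, LDA effect sizes, response categories.

Three layers, matching how three-group (control / stress / stress+drug)
microbiome studies are usually analysed:

* Kruskal-Wallis across all groups and pairwise two-group tests
  (Welch t by default, Mann-Whitney selectable) on relative abundances.
* An LDA-effect-size (LEfSe-style) screen: taxa passing the Kruskal-Wallis
  filter are scored by the magnitude of their contribution to a
  bootstrapped linear-discriminant separation of the groups, on a log10
  scale over abundances expressed per million.
* A response classification per taxon from the two pairwise contrasts
  control-vs-stress (pA, dA) and stress-vs-drug (pB, dB):

  restored     significant in both and the drug reverses the stress shift
  stress_only  shifted by stress, not reversed by the drug
  drug_only    unchanged by stress but shifted by the drug
  unchanged    everything else

p-values are reported raw by default (Benjamini-Hochberg optionally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, SampleMetadata

__all__ = [
    "FeatureTestResult",
    "LdaEffect",
    "ResponseCategory",
    "CATEGORIES",
    "kruskal_wallis",
    "two_group_test",
    "lda_effect_size",
    "classify_response",
    "classify_taxa",
    "test_all_taxa",
    "adjust_bh",
]

CATEGORIES = ("restored", "stress_only", "drug_only", "unchanged")

# LEfSe convention: abundances expressed per million before scoring, so the
# usual LDA-score threshold of 2.0 means a contribution of >= 100 ppm.
ABUNDANCE_SCALE = 1e6


@dataclass
class FeatureTestResult:
    taxon_id: str
    contrast: tuple[str, ...]
    statistic: float
    p_value: float
    direction: int | None = None  # sign(mean(group2) - mean(group1)); pairwise only


@dataclass
class LdaEffect:
    taxon_id: str
    enriched_group: str
    kw_p: float
    lda_score: float
    n_bootstraps: int


@dataclass
class ResponseCategory:
    taxon_id: str
    category: str
    p_control_stress: float
    d_control_stress: int
    p_stress_drug: float
    d_stress_drug: int


def _split_groups(values, labels, order=None):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    if order is None:
        order = list(dict.fromkeys(labels.tolist()))
    parts = [values[labels == g] for g in order]
    for g, part in zip(order, parts):
        if len(part) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return parts, list(order)


def kruskal_wallis(values, labels, taxon_id: str = "") -> FeatureTestResult:
    """Kruskal-Wallis H (midrank ties correction, chi-square p with k-1 df)."""
    parts, order = _split_groups(values, labels)
    if len(parts) < 2:
        raise ValueError("need at least 2 groups")
    flat = np.concatenate(parts)
    if np.all(flat == flat[0]):  # all observations identical: no evidence
        return FeatureTestResult(taxon_id, tuple(order), 0.0, 1.0)
    h, p = stats.kruskal(*parts)
    return FeatureTestResult(taxon_id, tuple(order), float(h), float(p))


def two_group_test(values, labels, pair=None, method: str = "t_test",
                   taxon_id: str = "") -> FeatureTestResult:
    """Two-sided two-group contrast.

    method "t_test" is Welch's unequal-variance t; "mann_whitney" uses the
    exact null distribution when both groups are small and tie-free.
    direction = sign(mean(group2) - mean(group1)) in the order of ``pair``.
    """
    parts, order = _split_groups(values, labels, order=pair)
    if len(parts) != 2:
        raise ValueError("two_group_test needs exactly 2 groups")
    a, b = parts
    direction = int(np.sign(b.mean() - a.mean()))
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return FeatureTestResult(taxon_id, tuple(order), 0.0, 1.0, 0)
        # deterministic separation: p is the method's limiting value
        if method == "t_test":
            return FeatureTestResult(taxon_id, tuple(order), np.inf, 0.0, direction)
    if method == "t_test":
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return FeatureTestResult(taxon_id, tuple(order), float(t), float(p), direction)
    if method == "mann_whitney":
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return FeatureTestResult(taxon_id, tuple(order), float(u), float(p), direction)
    raise ValueError(f"unknown method: {method!r}")


def test_all_taxa(t: AbundanceTable, m: SampleMetadata, pair=None,
                  method: str = "t_test") -> list[FeatureTestResult]:
    """Run a contrast for every taxon.

    With ``pair`` given, a two-group test restricted to those groups;
    otherwise Kruskal-Wallis across all declared groups.
    """
    m.validate_samples(t.sample_ids)
    labels = np.array([m.group_of(s) for s in t.sample_ids])
    results = []
    for i, taxon in enumerate(t.taxon_ids):
        row = t.values[i]
        if pair is not None:
            mask = np.isin(labels, pair)
            results.append(
                two_group_test(row[mask], labels[mask], pair=pair,
                               method=method, taxon_id=taxon)
            )
        else:
            results.append(kruskal_wallis(row, labels, taxon_id=taxon))
    return results


def _lda_direction(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit-norm LDA direction for binary y with ridge-regularized pooled cov."""
    n, f = x.shape
    mu1 = x[y].mean(axis=0)
    mu0 = x[~y].mean(axis=0)
    centered = x.copy()
    centered[y] -= mu1
    centered[~y] -= mu0
    sw = centered.T @ centered / max(n - 2, 1)
    ridge = 1e-3 * (np.trace(sw) / f if np.trace(sw) > 0 else 1.0) + 1e-12
    w = np.linalg.solve(sw + ridge * np.eye(f), mu1 - mu0)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def lda_effect_size(t: AbundanceTable, m: SampleMetadata, alpha: float = 0.05,
                    n_boot: int = 30, subsample_frac: float = 2 / 3,
                    lda_threshold: float = 2.0, seed: int | None = None,
                    ) -> list[LdaEffect]:
    """LEfSe-style two-stage differential abundance screen.

    Stage 1 keeps taxa with Kruskal-Wallis p < alpha across groups.
    Stage 2 bootstraps (class-stratified subsampling without replacement,
    fraction ``subsample_frac``), fits a regularized one-vs-rest linear
    discriminant on the retained taxa, and scores each taxon by its mean
    contribution |w_f * (mu_class_f - mu_rest_f)| to the projected
    class-mean separation, on abundances scaled per million.  The reported
    score is log10(1 + mean effect); taxa scoring >= ``lda_threshold`` are
    returned with the group in which their mean abundance is largest.
    """
    m.validate_samples(t.sample_ids)
    rng = np.random.default_rng(seed)
    labels = np.array([m.group_of(s) for s in t.sample_ids])
    groups = [g for g in m.group_order if g in set(labels)]
    kw = test_all_taxa(t, m)
    retained = [i for i, r in enumerate(kw) if r.p_value < alpha]
    if not retained:
        return []
    x_full = t.values[retained].T * ABUNDANCE_SCALE  # samples x features
    effects = np.zeros((n_boot, len(retained)))
    for b in range(n_boot):
        idx = []
        for g in groups:
            members = np.flatnonzero(labels == g)
            k = max(2, int(np.ceil(subsample_frac * len(members))))
            idx.extend(rng.choice(members, size=min(k, len(members)), replace=False))
        idx = np.array(idx)
        xb, yb = x_full[idx], labels[idx]
        per_class = []
        for g in groups:
            yg = yb == g
            if yg.all() or not yg.any():
                continue
            w = _lda_direction(xb, yg)
            per_class.append(np.abs(w * (xb[yg].mean(axis=0) - xb[~yg].mean(axis=0))))
        effects[b] = np.max(per_class, axis=0)
    scores = np.log10(1.0 + effects.mean(axis=0))
    out = []
    for j, i in enumerate(retained):
        if scores[j] >= lda_threshold:
            means = {g: t.values[i][labels == g].mean() for g in groups}
            out.append(
                LdaEffect(t.taxon_ids[i], max(means, key=means.get),
                          kw[i].p_value, float(scores[j]), n_boot)
            )
    out.sort(key=lambda e: -e.lda_score)
    return out


def classify_response(pA: float, dA: int, pB: float, dB: int,
                      alpha: float = 0.05, taxon_id: str = "") -> ResponseCategory:
    """Classify a taxon from control-vs-stress (pA, dA) and stress-vs-drug
    (pB, dB) contrasts.

    A significant drug contrast counts as a reversal only when its
    direction is exactly opposite the stress shift; direction 0 with a
    significant p is treated as non-reversal.
    """
    sigA = pA < alpha
    sigB = pB < alpha
    reversal = sigB and dA != 0 and dB == -dA
    if sigA and reversal:
        cat = "restored"
    elif sigA:
        cat = "stress_only"
    elif sigB:
        cat = "drug_only"
    else:
        cat = "unchanged"
    return ResponseCategory(taxon_id, cat, pA, int(dA), pB, int(dB))


def classify_taxa(t: AbundanceTable, m: SampleMetadata, control: str, stress: str,
                  drug: str, alpha: float = 0.05, method: str = "t_test",
                  ) -> list[ResponseCategory]:
    """Per-taxon response categories from the two pairwise contrasts."""
    a = test_all_taxa(t, m, pair=(control, stress), method=method)
    b = test_all_taxa(t, m, pair=(stress, drug), method=method)
    return [
        classify_response(ra.p_value, ra.direction, rb.p_value, rb.direction,
                          alpha=alpha, taxon_id=ra.taxon_id)
        for ra, rb in zip(a, b)
    ]


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (optional, off by default upstream)."""
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
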