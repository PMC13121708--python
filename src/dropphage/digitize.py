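"""Droplet digitization: lysed / non-lysed classification of green signals.

Droplet fluorescence populations are well described by log-normal modes, so a
Gaussian mixture is fitted to the natural-log green signals; the number of
components is chosen by BIC, components are sorted by mean, and by default
the single lowest-mean component is the negative (non-lysed) population.  The
positive fraction ``P_L`` is the summed weight of all higher modes (which
absorbs multi-lytic-cycle tiers naturally); hard-label and mean-posterior
variants are provided for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import silhouette_score as _sk_silhouette
from sklearn.mixture import GaussianMixture
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MixtureFit",
    "DropletDigitizer",
    "fit_mixture",
    "positive_fraction",
    "silhouette_score",
    "classify_with_control",
    "negative_reference",
    "timecourse_positive_fractions",
    "AmbiguousDigitizationError",
]

MIN_DROPLETS = 50


class AmbiguousDigitizationError(ValueError):
    """Single-component fit cannot be polarized without a negative control."""


@dataclass
class MixtureFit:
    """Result of a Gaussian-mixture digitization of log green signals.

    Components are sorted by log-space mean ascending; ``negative_components``
    indexes the components classed as non-lysed.  ``P_L`` is
    ``1 - sum(weights[negative_components])``.
    """

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    negative_components: tuple[int, ...]
    P_L: float
    hard_labels: np.ndarray
    component_labels: np.ndarray
    posterior_positive_mean: float
    n_droplets: int
    silhouette: float | None = None
    model_selection_trace: dict[int, float] = field(default_factory=dict)
    control_checked: bool = False

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")


def _sorted_gmm_params(gmm: GaussianMixture) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    means = gmm.means_.ravel()
    order = np.argsort(means, kind="stable")
    sds = np.sqrt(gmm.covariances_.reshape(-1))
    return order, gmm.weights_[order], means[order], sds[order]


class DropletDigitizer(BaseEstimator, ClassifierMixin):
    """Gaussian-mixture digitizer for droplet green fluorescence.

    Parameters
    ----------
    k_max : int
        Largest number of mixture components tried; K chosen by BIC over
        ``1..k_max``.
    merge_z : float
        Components whose means sit closer than ``merge_z`` times the smaller
        of their SDs are treated as fragments of one mode when building the
        negative set, so an over-split negative mode stays negative.  Set to
        0 to force the single lowest-mean component.
    min_support : float
        Components whose weight corresponds to fewer than this many droplets
        are discarded as EM artifacts before the negative set is chosen.
    random_state : int
        Seed for the mixture fits (k-means and quantile initializations are
        both tried per K; the better log-likelihood wins) and for silhouette
        subsampling.
    compute_silhouette : bool
        Whether to score the hard labels (subsampled, O(n^2) otherwise).
    silhouette_cap : int
        Subsample cap for the silhouette computation.

    Attributes
    ----------
    fit_ : MixtureFit
        Full digitization record.
    labels_ : ndarray of 0/1 hard assignments.
    """

    def __init__(
        self,
        k_max: int = 4,
        merge_z: float = 2.0,
        min_support: float = 5.0,
        random_state: int = 0,
        compute_silhouette: bool = False,
        silhouette_cap: int = 10_000,
    ) -> None:
        self.k_max = k_max
        self.merge_z = merge_z
        self.min_support = min_support
        self.random_state = random_state
        self.compute_silhouette = compute_silhouette
        self.silhouette_cap = silhouette_cap

    def _fit_k(self, logx: np.ndarray, k: int) -> GaussianMixture:
        # two deterministic starts per K (k-means and quantile placement);
        # the better log-likelihood wins
        common = dict(n_components=k, covariance_type="diag",
                      random_state=self.random_state, n_init=1,
                      reg_covar=1e-6, max_iter=500)
        cands = [GaussianMixture(init_params="kmeans", **common).fit(logx)]
        qs = (np.arange(k) + 0.5) / k
        cands.append(
            GaussianMixture(
                means_init=np.quantile(logx, qs).reshape(-1, 1),
                weights_init=np.full(k, 1.0 / k),
                **common,
            ).fit(logx)
        )
        return max(cands, key=lambda g: g.score(logx))

    def fit(self, X, y=None) -> "DropletDigitizer":
        x = np.asarray(X, dtype=float).ravel()
        if x.size < MIN_DROPLETS:
            raise ValueError(
                f"need at least {MIN_DROPLETS} droplets to digitize, got {x.size}"
            )
        if np.any(~np.isfinite(x)) or np.any(x <= 0):
            raise ValueError("green signals must be finite and positive")
        logx = np.log(x)[:, None]

        trace: dict[int, float] = {}
        best: GaussianMixture | None = None
        for k in range(1, self.k_max + 1):
            gmm = self._fit_k(logx, k)
            trace[k] = float(gmm.bic(logx))
            if best is None or trace[k] < trace[best.n_components]:
                best = gmm

        order, weights, means, sds = _sorted_gmm_params(best)
        resp = best.predict_proba(logx)[:, order]

        # components supported by fewer than ~min_support droplets are EM
        # artifacts (outlier singletons); drop them before deciding polarity
        support = self.min_support / x.size
        keep = weights >= support
        if not keep.all() and keep.any():
            weights, means, sds = weights[keep], means[keep], sds[keep]
            weights = weights / weights.sum()
            resp = resp[:, keep]
            resp = resp / resp.sum(axis=1, keepdims=True)
        k = weights.size

        n_neg = 1
        while (n_neg < k and means[n_neg] - means[n_neg - 1]
               < self.merge_z * min(sds[n_neg], sds[n_neg - 1])):
            n_neg += 1
        neg = tuple(range(n_neg))
        comp = np.argmax(resp, axis=1).astype(np.int8)
        post_pos = resp[:, n_neg:].sum(axis=1) if n_neg < k else np.zeros(x.size)
        hard = (post_pos > 0.5).astype(np.int8)
        p_l = float(1.0 - weights[:n_neg].sum()) if n_neg < k else 0.0

        sil = None
        if self.compute_silhouette and len(np.unique(hard)) > 1:
            sil = silhouette_score(
                logx.ravel(), hard, subsample_cap=self.silhouette_cap,
                seed=self.random_state,
            )
        self.fit_ = MixtureFit(
            n_components=k,
            weights=weights,
            means=means,
            sds=sds,
            negative_components=neg,
            P_L=p_l,
            hard_labels=hard,
            component_labels=comp,
            posterior_positive_mean=float(post_pos.mean()),
            n_droplets=x.size,
            silhouette=sil,
            model_selection_trace=trace,
        )
        self.labels_ = hard
        self.log_signals_ = logx.ravel()
        return self

    def predict(self, X) -> np.ndarray:
        """Hard 0/1 labels for new signals under the fitted mixture."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "fit_")
        x = np.log(np.asarray(X, dtype=float).ravel())
        f = self.fit_
        # posterior under the stored (sorted) parameters
        log_dens = (
            -0.5 * ((x[:, None] - f.means) / f.sds) ** 2
            - np.log(f.sds)
            + np.log(f.weights)
        )
        log_dens -= log_dens.max(axis=1, keepdims=True)
        dens = np.exp(log_dens)
        n_neg = len(f.negative_components)
        post_pos = dens[:, n_neg:].sum(axis=1) / dens.sum(axis=1)
        return (post_pos > 0.5).astype(np.int8)


def fit_mixture(green_signals, k_max: int = 4, seed: int = 0,
                compute_silhouette: bool = False) -> MixtureFit:
    """Fit a BIC-selected Gaussian mixture to log green signals."""
    dig = DropletDigitizer(k_max=k_max, random_state=seed,
                           compute_silhouette=compute_silhouette)
    return dig.fit(green_signals).fit_


def positive_fraction(
    fit: MixtureFit, method: str = "weights", confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Positive fraction P_L with a Wilson interval at the droplet count.

    ``weights`` (default) sums the mixture weights of all non-negative
    components; ``hard`` uses the hard-label fraction; ``posterior`` the mean
    positive posterior probability.
    """
    if fit.n_components == 1 and not fit.control_checked:
        raise AmbiguousDigitizationError(
            "a single-component mixture cannot distinguish all-negative from "
            "all-positive; classify against a phage-free control "
            "(classify_with_control) first"
        )
    if method == "weights":
        p = fit.P_L
    elif method == "hard":
        p = float(np.mean(fit.hard_labels))
    elif method == "posterior":
        p = fit.posterior_positive_mean
    else:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = proportion_confint(
        count=p * fit.n_droplets, nobs=fit.n_droplets,
        alpha=1 - confidence, method="wilson",
    )
    return p, (float(lo), float(hi))


def silhouette_score(
    log_signals, hard_labels, subsample_cap: int = 10_000, seed: int = 0
) -> float:
    """Mean silhouette coefficient of the 0/1 digitization on 1-D log signals.

    Subsampled above ``subsample_cap`` points (the metric is O(n^2)).
    """
    x = np.asarray(log_signals, dtype=float).ravel()
    labels = np.asarray(hard_labels).ravel()
    if subsample_cap < 100:
        raise ValueError("subsample_cap must be >= 100")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette score undefined for a single class")
    if x.size > subsample_cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(x.size, size=subsample_cap, replace=False)
        x, labels = x[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            raise ValueError("subsample collapsed to a single class")
    return float(_sk_silhouette(x[:, None], labels))


def negative_reference(fit: MixtureFit) -> MixtureFit:
    """Extract a fit's negative mode as a stand-in control.

    Useful for time courses: a late, clearly multimodal aliquot pins down the
    negative-mode position, which then polarizes early all-negative (K = 1)
    aliquots via :func:`classify_with_control`.
    """
    if not fit.negative_components:
        raise ValueError("fit has no negative components to reference")
    idx = list(fit.negative_components)
    dom = idx[int(np.argmax(fit.weights[idx]))]
    return MixtureFit(
        n_components=1,
        weights=np.array([1.0]),
        means=fit.means[[dom]],
        sds=fit.sds[[dom]],
        negative_components=(0,),
        P_L=0.0,
        hard_labels=np.zeros(0, dtype=np.int8),
        component_labels=np.zeros(0, dtype=np.int8),
        posterior_positive_mean=0.0,
        n_droplets=fit.n_droplets,
        control_checked=True,
    )


def classify_with_control(
    sample_fit: MixtureFit, control_fit: MixtureFit, z: float = 3.0
) -> MixtureFit:
    """Re-polarize a mixture fit against a phage-free control emulsion.

    Components whose means lie within ``z`` control SDs of the control's
    dominant mode are classed negative.  Resolves the K = 1 ambiguity
    (all-negative vs all-positive) and heavy spontaneous-lysis tails.
    """
    dom = int(np.argmax(control_fit.weights))
    mu0, sd0 = control_fit.means[dom], control_fit.sds[dom]
    neg = tuple(
        i for i, m in enumerate(sample_fit.means) if abs(m - mu0) <= z * sd0
    )
    neg_mask = np.zeros(sample_fit.n_components, dtype=bool)
    neg_mask[list(neg)] = True
    p_l = float(sample_fit.weights[~neg_mask].sum())
    hard = (~neg_mask[sample_fit.component_labels]).astype(np.int8)
    return MixtureFit(
        n_components=sample_fit.n_components,
        weights=sample_fit.weights,
        means=sample_fit.means,
        sds=sample_fit.sds,
        negative_components=neg,
        P_L=p_l,
        hard_labels=hard,
        component_labels=sample_fit.component_labels,
        posterior_positive_mean=p_l,
        n_droplets=sample_fit.n_droplets,
        silhouette=sample_fit.silhouette,
        model_selection_trace=sample_fit.model_selection_trace,
        control_checked=True,
    )


def timecourse_positive_fractions(
    green_series,
    k_max: int = 4,
    seed: int = 0,
    method: str = "weights",
    control_fit: MixtureFit | None = None,
) -> list[tuple[float, tuple[float, float], int]]:
    """Digitize a series of aliquots, polarizing all-negative early ones.

    Pre-lag aliquots contain no positives, so their mixtures collapse to a
    single component that cannot be polarized in isolation.  The aliquot with
    the most mixture components (latest on ties) supplies the negative-mode
    reference; an explicit ``control_fit`` overrides it.

    Returns one (P_L, (ci_low, ci_high), n) triple per aliquot.
    """
    fits = [
        fit_mixture(g, k_max=k_max, seed=seed + i)
        for i, g in enumerate(green_series)
    ]
    reference = control_fit
    if reference is None:
        multi = [f for f in fits if f.n_components > 1]
        if multi:
            best_k = max(f.n_components for f in multi)
            reference = negative_reference(
                [f for f in multi if f.n_components == best_k][-1]
            )
    out = []
    for fit in fits:
        if fit.n_components == 1:
            if reference is None:
                raise AmbiguousDigitizationError(
                    "every aliquot is single-mode; provide a control_fit to "
                    "polarize the series"
                )
            fit = classify_with_control(fit, reference)
        p, ci = positive_fraction(fit, method=method)
        out.append((p, ci, fit.n_droplets))
    return out
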