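"""Synthetic-data quality scores: Jensen-Shannon divergence and Fréchet distance.

Both scores compare two tabular samples of the 10 predictor features.

JS divergence is estimated per feature from equal-width histograms over the
pooled range, ``JS = [KL(P||m) + KL(Q||m)] / 2`` with base-2 logarithms and
``m`` the pointwise mean of P and Q, then averaged across features — bounded
in [0, 1], 0 for identical distributions.

The Fréchet distance treats each sample as a Gaussian summarized by its mean
vector and covariance matrix:

    d^2 = ||mu_P - mu_Q||^2 + Tr(C_P + C_Q - 2 (C_P C_Q)^{1/2})

Computed on raw tabular features (no embedding network); the conventional
name "FID" is kept.  Features are z-scored by the reference sample before
scoring so mmHg and liters contribute comparably.  Lower is better; the
score is sensitive to mode collapse.
"""

from __future__ import annotations

import numpy as np

from .schema import CLASS_HIGH, CLASS_LOW, LabeledDataset, ValidationError

JS_EPSILON = 1e-10
COV_EPSILON = 1e-12


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, LabeledDataset):
        return data.features
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def js_from_histograms(p: np.ndarray, q: np.ndarray, eps: float = JS_EPSILON) -> float:
    """JS divergence (base 2) of two probability vectors sharing bin edges."""
    p = np.asarray(p, dtype=float) + eps
    q = np.asarray(q, dtype=float) + eps
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    kl_pm = np.sum(p * np.log2(p / m))
    kl_qm = np.sum(q * np.log2(q / m))
    return float(0.5 * (kl_pm + kl_qm))


def js_divergence(A, B, bins: int = 10, eps: float = JS_EPSILON) -> float:
    """Mean per-feature histogram JS divergence between two samples, in [0, 1]."""
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    X, Y = _as_matrix(A), _as_matrix(B)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValidationError("both samples must be non-empty")
    if X.shape[1] != Y.shape[1]:
        raise ValidationError("samples must share the feature schema")
    scores = []
    for j in range(X.shape[1]):
        lo = min(X[:, j].min(), Y[:, j].min())
        hi = max(X[:, j].max(), Y[:, j].max())
        if hi <= lo:  # pooled feature is constant: identical point masses
            scores.append(0.0)
            continue
        edges = np.linspace(lo, hi, bins + 1)
        p, _ = np.histogram(X[:, j], bins=edges)
        q, _ = np.histogram(Y[:, j], bins=edges)
        scores.append(js_from_histograms(p / p.sum(), q / q.sum(), eps))
    return float(np.mean(scores))


def js_between_classes(S: LabeledDataset, bins: int = 10) -> float:
    """JS divergence between the class-high and class-low subsets of one sample."""
    counts = S.class_counts()
    if counts[CLASS_HIGH] == 0 or counts[CLASS_LOW] == 0:
        raise ValidationError("both classes must be present")
    return js_divergence(S.subset_class(CLASS_HIGH), S.subset_class(CLASS_LOW), bins=bins)


def js_between_classes_cross(A: LabeledDataset, B: LabeledDataset, bins: int = 10) -> float:
    """Alternative reading: mean JS between same-class subsets of two samples."""
    scores = []
    for cls in (CLASS_HIGH, CLASS_LOW):
        a, b = A.subset_class(cls), B.subset_class(cls)
        if a.n == 0 or b.n == 0:
            raise ValidationError(f"class {cls!r} absent from one sample")
        scores.append(js_divergence(a, b, bins=bins))
    return float(np.mean(scores))


def _sqrtm_psd(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    return (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T


def frechet_distance(
    X, Y, eps: float = COV_EPSILON, variant: str = "standard"
) -> float:
    """Fréchet distance between the Gaussian moment summaries of two samples.

    ``variant="standard"`` is the usual ``Tr(C_P + C_Q - 2 (C_P C_Q)^{1/2})``
    trace term, with ``Tr((C_P C_Q)^{1/2})`` evaluated through the symmetric
    form ``Tr((C_P^{1/2} C_Q C_P^{1/2})^{1/2})`` and tiny negative eigenvalues
    clipped to zero.  ``variant="printed"`` evaluates the non-distance
    ``+2 C_P C_Q`` trace term and exists only for auditability.
    """
    X, Y = _as_matrix(X), _as_matrix(Y)
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValidationError("need n >= 2 per sample for a covariance")
    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    k = X.shape[1]
    reg = eps * np.eye(k)
    Cx = np.atleast_2d(np.cov(X, rowvar=False)) + reg
    Cy = np.atleast_2d(np.cov(Y, rowvar=False)) + reg
    diff = float(np.sum((mu_x - mu_y) ** 2))
    if variant == "printed":
        trace = float(np.trace(Cx + Cy + 2.0 * Cx @ Cy))
    elif variant == "standard":
        rx = _sqrtm_psd(Cx)
        inner = rx @ Cy @ rx
        w = np.linalg.eigvalsh(0.5 * (inner + inner.T))
        tr_sqrt = float(np.sum(np.sqrt(np.clip(w, 0.0, None))))
        trace = float(np.trace(Cx) + np.trace(Cy) - 2.0 * tr_sqrt)
    else:
        raise ValidationError(f"unknown variant {variant!r}")
    d = diff + trace
    if not np.isfinite(d):
        raise ValidationError(
            f"non-finite Fréchet distance (diff={diff}, trace={trace})"
        )
    return max(d, 0.0) if variant == "standard" else d


def fid_score(
    A,
    B,
    standardize: bool = True,
    pooled: bool = False,
    variant: str = "standard",
) -> float:
    """Fréchet distance between two samples on (optionally z-scored) features.

    By default features are standardized using the moments of ``A`` (the
    reference/real sample); ``pooled=True`` standardizes by the stacked
    samples instead, which makes the score symmetric in its arguments.
    """
    X, Y = _as_matrix(A), _as_matrix(B)
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValidationError("need n >= 2 per sample")
    if standardize:
        ref = np.vstack([X, Y]) if pooled else X
        mu = ref.mean(axis=0)
        sd = ref.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
        Y = (Y - mu) / sd
    return frechet_distance(X, Y, variant=variant)
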