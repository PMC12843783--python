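"""Non-negative trilinear (PARAFAC) decomposition of an EEM stack.

The stack of preprocessed EEMs forms a sample x excitation x emission
tensor that is modelled as a sum of F rank-one components,

    X[i, x, m] ~= sum_f A[i, f] * C[x, f] * B[m, f],

with nonnegativity on all three modes: A holds per-sample concentration
scores, C excitation loadings and B emission loadings.  Fitting is
alternating least squares with random restarts; cells excised during
scatter removal are treated as missing via expectation-maximisation
(model values are imputed between sweeps, and the objective is the sum
of squared errors over observed cells only).

Validation mirrors chemometric practice for DOM fluorescence: the core
consistency diagnostic (CORCONDIA) for rank selection, split-half
resampling with Tucker-congruence matching, and residual inspection.
Component scale is reported as Fmax — with B and C normalised to unit
maximum, the score matrix A is directly the maximum fluorescence
intensity of each component in each sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.optimize import nnls

from .eem import EEMSpectrum

PROTEIN_LIKE = "protein-like"
HUMIC_LIKE = "humic-like"


class PARAFACError(ValueError):
    pass


@dataclass
class EEMStack:
    """A list of EEMs on a common wavelength grid, stacked into a tensor.

    ``tensor`` is sample x ex x em with NaN at masked cells.
    """

    samples: list[EEMSpectrum]
    ex: np.ndarray = field(init=False)
    em: np.ndarray = field(init=False)
    tensor: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise PARAFACError("an EEM stack needs at least 2 samples")
        first = self.samples[0]
        for s in self.samples[1:]:
            if (s.ex.size != first.ex.size or s.em.size != first.em.size
                    or not np.allclose(s.ex, first.ex)
                    or not np.allclose(s.em, first.em)):
                raise PARAFACError(
                    f"sample {s.sample_id}: wavelength grid differs from "
                    f"{first.sample_id}")
        self.ex = first.ex.copy()
        self.em = first.em.copy()
        self.tensor = np.stack([s.masked_intensity() for s in self.samples])
        for s, grid in zip(self.samples, self.tensor):
            if np.all(np.isnan(grid)):
                raise PARAFACError(f"sample {s.sample_id} is entirely masked")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape


@dataclass
class PARAFACModel:
    """Fitted PARAFAC model in canonical form.

    Emission (B) and excitation (C) loading columns are scaled to unit
    maximum, with all scale absorbed into the score matrix A, so
    ``A[i, f]`` is the component's Fmax in sample i (input units).
    """

    n_components: int
    A: np.ndarray            # sample x F scores / Fmax
    B: np.ndarray            # em x F emission loadings, unit max
    C: np.ndarray            # ex x F excitation loadings, unit max
    ex: np.ndarray
    em: np.ndarray
    sample_ids: list[str]
    sse: float
    total_ss: float
    n_iter: int
    corcondia: float | None = None
    split_half: dict | None = None
    sse_history: list[float] = field(default_factory=list)

    @property
    def component_labels(self) -> list[str]:
        return [f"C{f + 1}" for f in range(self.n_components)]

    @property
    def explained_variance(self) -> float:
        return 1.0 - self.sse / self.total_ss if self.total_ss > 0 else np.nan

    def reconstruct(self) -> np.ndarray:
        return np.einsum("if,xf,mf->ixm", self.A, self.C, self.B)

    def fmax_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.sample_ids,
                            columns=self.component_labels)


# ---------------------------------------------------------------------------
# congruence / matching utilities
# ---------------------------------------------------------------------------

def tucker_congruence(x: np.ndarray, y: np.ndarray) -> float:
    """Normalised inner product |<x,y>| / (||x|| ||y||)."""
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(abs(np.dot(x, y)) / (nx * ny))


def match_components(B_ref: np.ndarray, B_other: np.ndarray,
                     C_ref: np.ndarray | None = None,
                     C_other: np.ndarray | None = None) -> list[int]:
    """Greedy maximum-congruence pairing of components across two fits.

    Matching is on the emission mode, ties broken by excitation
    congruence; returns ``perm`` such that column ``perm[f]`` of the
    other fit corresponds to column ``f`` of the reference.
    """
    F = B_ref.shape[1]
    cong = np.array([[tucker_congruence(B_ref[:, i], B_other[:, j])
                      for j in range(F)] for i in range(F)])
    tie = np.zeros_like(cong)
    if C_ref is not None and C_other is not None:
        tie = np.array([[tucker_congruence(C_ref[:, i], C_other[:, j])
                         for j in range(F)] for i in range(F)])
    perm = [-1] * F
    used: set[int] = set()
    order = sorted(
        ((cong[i, j], tie[i, j], i, j) for i in range(F) for j in range(F)),
        reverse=True)
    for _, _, i, j in order:
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    return perm


# ---------------------------------------------------------------------------
# ALS core
# ---------------------------------------------------------------------------

def _nnls_rows(G: np.ndarray, CtX: np.ndarray) -> np.ndarray:
    """Solve min ||M w - x||, w >= 0 for many right-hand sides.

    Works from the Gram matrix G = M'M (F x F) and cross products
    CtX[:, r] = M'x_r, via the Cholesky square-root reformulation, so the
    cost per row is independent of the mode dimensions.
    """
    F = G.shape[0]
    # ridge for numerically singular Grams (e.g. a collapsed component)
    jitter = 1e-12 * max(np.trace(G), 1.0)
    R = cholesky(G + jitter * np.eye(F), lower=False)
    out = np.empty((CtX.shape[1], F))
    Rinv_t = np.linalg.inv(R).T
    for r in range(CtX.shape[1]):
        b = Rinv_t @ CtX[:, r]
        out[r], _ = nnls(R, b)
    return out


def _als_single(X: np.ndarray, observed: np.ndarray, F: int,
                rng: np.random.Generator, tol: float,
                max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                        float, int, list[float]]:
    """One ALS run from a random start.

    Returns (A, C, B, sse, n_iter, sse_history).
    """
    I, J, K = X.shape
    fill_value = np.nanmean(X[observed]) if observed.any() else 0.0
    Xf = np.where(observed, X, fill_value)
    A = rng.uniform(0.1, 1.0, size=(I, F))
    C = rng.uniform(0.1, 1.0, size=(J, F))
    B = rng.uniform(0.1, 1.0, size=(K, F))
    sse_prev = np.inf
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # revive collapsed components: a column zeroed by NNLS stays dead
        # under ALS, so it is reinitialised (standard NN-ALS safeguard)
        for M in (A, C, B):
            scale = M.max()
            for f in range(F):
                if M[:, f].max() <= 1e-12 * max(scale, 1e-300):
                    M[:, f] = rng.uniform(0.1, 1.0, size=M.shape[0])
        # mode updates on the EM-completed tensor
        G = (C.T @ C) * (B.T @ B)
        MtX = np.einsum("xf,mf,ixm->fi", C, B, Xf)
        A = _nnls_rows(G, MtX)
        G = (A.T @ A) * (B.T @ B)
        MtX = np.einsum("if,mf,ixm->fx", A, B, Xf)
        C = _nnls_rows(G, MtX)
        G = (A.T @ A) * (C.T @ C)
        MtX = np.einsum("if,xf,ixm->fm", A, C, Xf)
        B = _nnls_rows(G, MtX)
        model = np.einsum("if,xf,mf->ixm", A, C, B)
        resid = X[observed] - model[observed]
        sse = float(resid @ resid)
        history.append(sse)
        Xf = np.where(observed, X, model)  # E-step
        if sse_prev - sse <= tol * max(sse_prev, 1e-300) and n_iter > 1:
            sse_prev = sse
            break
        sse_prev = sse
    return A, C, B, sse_prev, n_iter, history


def _canonicalize(A: np.ndarray, B: np.ndarray,
                  C: np.ndarray, em: np.ndarray,
                  ex: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale B, C columns to unit maximum (scale into A); order components
    by emission then excitation peak position for deterministic labels."""
    A, B, C = A.copy(), B.copy(), C.copy()
    for f in range(A.shape[1]):
        bmax, cmax = B[:, f].max(), C[:, f].max()
        if bmax > 0:
            B[:, f] /= bmax
        if cmax > 0:
            C[:, f] /= cmax
        A[:, f] *= bmax * cmax
    order = sorted(range(A.shape[1]),
                   key=lambda f: (em[np.argmax(B[:, f])],
                                  ex[np.argmax(C[:, f])]))
    return A[:, order], B[:, order], C[:, order]


def fit_parafac(stack: EEMStack, n_components: int, n_starts: int = 10,
                tol: float = 1e-8, max_iter: int = 2500,
                seed: int = 0) -> PARAFACModel:
    """Fit a non-negative PARAFAC model to an EEM stack.

    Runs ``n_starts`` random ALS initialisations and keeps the best fit
    (lowest observed-cell SSE).  Masked cells are excluded from the
    objective via EM imputation; nonnegativity is enforced on all three
    modes by row-wise NNLS.
    """
    X = stack.tensor
    I, J, K = X.shape
    if n_components < 1:
        raise PARAFACError("n_components must be >= 1")
    if n_components > min(I, J, K):
        raise PARAFACError(
            f"rank {n_components} exceeds smallest mode length {min(I, J, K)}")
    observed = ~np.isnan(X)
    need = n_components * (J + K)
    for i, sid in enumerate(stack.sample_ids):
        n_obs = int(observed[i].sum())
        if n_obs <= need:
            raise PARAFACError(
                f"sample {sid}: only {n_obs} unmasked cells; need more than "
                f"{need} for rank {n_components}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_starts)):
        A, C, B, sse, n_iter, history = _als_single(
            X, observed, n_components, rng, tol, max_iter)
        if best is None or sse < best[3]:
            best = (A, C, B, sse, n_iter, history)
    A, C, B, sse, n_iter, history = best
    A, B, C = _canonicalize(A, B, C, stack.em, stack.ex)
    total_ss = float(np.nansum(X[observed] ** 2))
    return PARAFACModel(
        n_components=n_components, A=A, B=B, C=C,
        ex=stack.ex.copy(), em=stack.em.copy(),
        sample_ids=stack.sample_ids, sse=sse, total_ss=total_ss,
        n_iter=n_iter, sse_history=history)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def corcondia(model: PARAFACModel, stack: EEMStack) -> float:
    """Core consistency diagnostic, in percent (may be negative).

    The least-squares Tucker core G of the data against the fitted
    loadings is compared with the superdiagonal identity core T:
    ``100 * (1 - sum((g - t)^2) / sum(t^2))``.  A value near 100 supports
    the trilinear model at this rank; overfactored models collapse
    towards zero or below.  Missing cells are imputed from the model
    before the core is computed.
    """
    A, B, C = (_canonicalize(model.A, model.B, model.C, model.em, model.ex))
    F = model.n_components
    for name, M in (("sample", A), ("emission", B), ("excitation", C)):
        s = np.linalg.svd(M, compute_uv=False)
        if s[-1] < 1e-12 * s[0]:
            raise PARAFACError(
                f"{name} loadings are singular; reduce the model rank")
    X = stack.tensor
    observed = ~np.isnan(X)
    Xf = np.where(observed, X, np.einsum("if,xf,mf->ixm", A, C, B))
    Ai, Ci, Bi = (np.linalg.pinv(A), np.linalg.pinv(C), np.linalg.pinv(B))
    G = np.einsum("fi,gx,hm,ixm->fgh", Ai, Ci, Bi, Xf)
    T = np.zeros((F, F, F))
    for f in range(F):
        T[f, f, f] = 1.0
    return float(100.0 * (1.0 - ((G - T) ** 2).sum() / F))


def split_half_validate(stack: EEMStack, n_components: int,
                        scheme: str = "alternating", seed: int = 0,
                        n_starts: int = 5, tol: float = 1e-8,
                        max_iter: int = 2500,
                        congruence_threshold: float = 0.95) -> dict:
    """Split-half validation of a PARAFAC rank.

    Samples are split into two halves (``alternating`` by sorted sample
    id, or ``random``), each half fitted independently, and the emission
    and excitation loadings compared after greedy congruence matching.
    Returns the per-mode minimum Tucker congruence and a validation flag
    (both minima above ``congruence_threshold``).
    """
    n = len(stack.samples)
    if n < 4:
        raise PARAFACError("split-half validation needs at least 4 samples")
    order = sorted(range(n), key=lambda i: stack.sample_ids[i])
    if scheme == "alternating":
        half1 = order[0::2]
        half2 = order[1::2]
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(order)
        half1 = list(perm[: n // 2])
        half2 = list(perm[n // 2:])
    else:
        raise PARAFACError(f"unknown split scheme {scheme!r}")
    if min(len(half1), len(half2)) < 2:
        raise PARAFACError("each half needs at least 2 samples")
    fits = []
    for k, idx in enumerate((half1, half2)):
        sub = EEMStack([stack.samples[i] for i in idx])
        fits.append(fit_parafac(sub, n_components, n_starts=n_starts,
                                tol=tol, max_iter=max_iter, seed=seed + k))
    m1, m2 = fits
    perm = match_components(m1.B, m2.B, m1.C, m2.C)
    em_cong = [tucker_congruence(m1.B[:, f], m2.B[:, perm[f]])
               for f in range(n_components)]
    ex_cong = [tucker_congruence(m1.C[:, f], m2.C[:, perm[f]])
               for f in range(n_components)]
    result = {
        "scheme": scheme,
        "emission_congruence": em_cong,
        "excitation_congruence": ex_cong,
        "min_congruence": {"emission": float(min(em_cong)),
                           "excitation": float(min(ex_cong))},
        "validated": bool(min(min(em_cong), min(ex_cong))
                          > congruence_threshold),
    }
    return result


def compute_fmax(model: PARAFACModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fmax and percent abundance per sample and component.

    With emission/excitation loadings at unit maximum, a component's
    Fmax in a sample is its score ``A[i, f]``; percent abundance is
    Fmax normalised to 100 within each sample.  All-zero samples get
    missing percentages.  Models not in canonical form are
    canonicalised first, so Fmax is always in input intensity units.
    """
    A, B, C = _canonicalize(model.A, model.B, model.C, model.em, model.ex)
    fmax = pd.DataFrame(A, index=model.sample_ids,
                        columns=model.component_labels)
    totals = fmax.sum(axis=1)
    percent = 100.0 * fmax.div(totals.where(totals > 0), axis=0)
    return fmax, percent


def classify_components(model: PARAFACModel,
                        em_threshold: float = 380.0) -> pd.DataFrame:
    """Peak table: per component, emission peak, excitation peaks, class.

    The emission peak is the loading argmax; excitation peaks are all
    local maxima at >= 50% of the global maximum.  Components with an
    emission peak below ``em_threshold`` nm are protein-like, at or
    above it humic-like (flat loadings are 'unresolved').
    """
    rows = []
    for f, label in enumerate(model.component_labels):
        b, c = model.B[:, f], model.C[:, f]
        if np.ptp(b) == 0 or np.ptp(c) == 0:
            rows.append({"component": label, "em_peak": np.nan,
                         "ex_peaks": [], "class": "unresolved"})
            continue
        em_peak = float(model.em[int(np.argmax(b))])
        peaks = []
        cmax = c.max()
        for j in range(c.size):
            left = c[j - 1] if j > 0 else -np.inf
            right = c[j + 1] if j < c.size - 1 else -np.inf
            if c[j] >= left and c[j] > right and c[j] >= 0.5 * cmax:
                peaks.append(float(model.ex[j]))
        cls = PROTEIN_LIKE if em_peak < em_threshold else HUMIC_LIKE
        rows.append({"component": label, "em_peak": em_peak,
                     "ex_peaks": peaks, "class": cls})
    return pd.DataFrame(rows).set_index("component")
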