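"""MVAR effective connectivity: generalized orthogonalized PDC (gOPDC).

The measure follows the spectral MVAR chain: fit a multivariate
autoregressive model y(n) = sum_r A_r y(n-r) + w(n), transform the
coefficients to the frequency domain A(f) = I - sum_r A_r exp(-j 2 pi f
r / rate), and form, for each directed pair q -> p (p != q),

    gOPDC_pq(f) = (1 / lambda_pp^2)
                  * |Re A_pq(f)| / (a_q(f)^H Sigma_w^-1 a_q(f))
                  * |Im A_pq(f)| / (a_q(f)^H Sigma_w^-1 a_q(f))

where lambda_pp are the diagonal entries of the innovation covariance
Sigma_w and a_q(f) is the q-th column of A(f).  Multiplying the real- and
imaginary-part terms suppresses zero-lag (volume-conduction-like)
co-variability: an interaction whose cross-coefficient is purely real at a
frequency scores zero there.  Time variation is obtained by refitting on
sliding windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_core import EEGRecording

#: Reporting bands (Hz): low, medium and high frequency.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "low": (4.0, 12.0),
    "medium": (12.0, 30.0),
    "high": (30.0, 50.0),
}


class SingularFitError(ValueError):
    """MVAR regression is rank deficient (too few samples or collinear data)."""


@dataclass
class MVARModel:
    """Fitted MVAR: order ``m``, coefficient matrices and innovation covariance."""

    order: int
    coeffs: list[np.ndarray]          # m matrices, each ch x ch
    noise_cov: np.ndarray             # Sigma_w, ch x ch
    rate: float = 1000.0

    @property
    def n_channels(self) -> int:
        return self.noise_cov.shape[0]

    @property
    def lambda_diag(self) -> np.ndarray:
        """Diagonal of Sigma_w (per-channel innovation variance)."""
        return np.diag(self.noise_cov)


@dataclass
class SpectralMatrix:
    """A(f) for a frequency grid; ``values[k]`` is the ch x ch matrix at freqs[k]."""

    values: np.ndarray                # n_freq x ch x ch complex
    freqs: np.ndarray                 # Hz


@dataclass
class GOPDCMap:
    """Directed-interaction map: ``values[p, q, k]`` is flow q -> p at freqs[k].

    Diagonal entries are NaN (self-flow undefined).
    """

    values: np.ndarray                # ch x ch x n_freq
    freqs: np.ndarray


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_mvar(data: np.ndarray | EEGRecording, order: int,
             rate: float | None = None) -> MVARModel:
    """Least-squares MVAR fit of ``data`` (channels x samples), de-meaned.

    Builds the lagged regressor matrix and solves the multivariate
    regression; the residual covariance is reported as Sigma_w.
    """
    if isinstance(data, EEGRecording):
        rate = data.rate
        data = data.data
    if rate is None:
        rate = 1000.0
    y = np.asarray(data, dtype=float)
    ch, n = y.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= ch * order:
        raise SingularFitError(
            f"{n} samples cannot identify a {ch}-channel MVAR({order})"
        )
    y = y - y.mean(axis=1, keepdims=True)

    n_eff = n - order
    # regressors: [y(t-1); ...; y(t-m)] stacked as n_eff x (ch*m)
    X = np.empty((n_eff, ch * order))
    for r in range(1, order + 1):
        X[:, (r - 1) * ch:r * ch] = y[:, order - r:n - r].T
    Y = y[:, order:].T                                  # n_eff x ch

    rank = np.linalg.matrix_rank(X)
    if rank < ch * order:
        raise SingularFitError(
            f"regressor matrix rank {rank} < {ch * order}; data are collinear"
        )
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)           # (ch*m) x ch
    resid = Y - X @ B
    sigma = resid.T @ resid / (n_eff - ch * order)
    coeffs = [B[(r - 1) * ch:r * ch, :].T for r in range(1, order + 1)]
    return MVARModel(order=order, coeffs=coeffs, noise_cov=sigma, rate=rate)


def select_order(data: np.ndarray | EEGRecording, max_order: int = 10,
                 rate: float | None = None,
                 orders=None) -> int:
    """Model order minimizing AIC = ln det(Sigma_w) + 2 m ch^2 / N.

    Candidates are 1..max_order unless an explicit ``orders`` iterable is
    given.
    """
    if isinstance(data, EEGRecording):
        rate = data.rate
        data = data.data
    y = np.asarray(data, dtype=float)
    ch, n = y.shape
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    candidates = sorted(orders) if orders is not None else range(1, max_order + 1)
    best_m, best_aic = min(candidates), np.inf
    for m in candidates:
        model = fit_mvar(y, m, rate=rate)
        sign, logdet = np.linalg.slogdet(model.noise_cov)
        if sign <= 0:
            continue
        aic = logdet + 2.0 * m * ch * ch / n
        if aic < best_aic:
            best_aic, best_m = aic, m
    return best_m


# ---------------------------------------------------------------------------
# Spectral transform and gOPDC
# ---------------------------------------------------------------------------

def spectral_matrix(model: MVARModel,
                    freqs: np.ndarray | None = None) -> SpectralMatrix:
    """A(f) = I - sum_r A_r exp(-j 2 pi f r / rate) on a frequency grid."""
    if freqs is None:
        freqs = default_freq_grid(model.rate)
    freqs = np.asarray(freqs, dtype=float)
    ch = model.n_channels
    values = np.empty((freqs.size, ch, ch), dtype=complex)
    eye = np.eye(ch)
    for k, f in enumerate(freqs):
        acc = eye.astype(complex).copy()
        for r, a in enumerate(model.coeffs, start=1):
            acc -= a * np.exp(-2j * np.pi * f * r / model.rate)
        values[k] = acc
    return SpectralMatrix(values=values, freqs=freqs)


def default_freq_grid(rate: float) -> np.ndarray:
    """1 Hz spacing from 1 Hz up to (not including) Nyquist."""
    return np.arange(1.0, rate / 2.0)


def gopdc(model: MVARModel, freqs: np.ndarray | None = None,
          sqrt_denominator: bool = False,
          reg: float = 1e-12) -> GOPDCMap:
    """Generalized orthogonalized PDC of a fitted MVAR model.

    ``sqrt_denominator=True`` switches to the classical square-root (GPDC)
    normalization of each factor for comparison.
    """
    spec = spectral_matrix(model, freqs)
    sigma = model.noise_cov
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        warnings.warn("singular innovation covariance; applying ridge "
                      "regularization", RuntimeWarning, stacklevel=2)
        ridge = reg * np.trace(sigma) / sigma.shape[0]
        sigma_inv = np.linalg.inv(sigma + ridge * np.eye(sigma.shape[0]))
    lam = np.diag(sigma)
    ch = model.n_channels
    n_f = spec.freqs.size
    out = np.empty((ch, ch, n_f))
    for k in range(n_f):
        A = spec.values[k]
        # denominator per column q: a_q^H Sigma_w^-1 a_q (real positive)
        denom = np.real(np.einsum("iq,ij,jq->q", A.conj(), sigma_inv, A))
        denom = np.maximum(denom, reg)
        if sqrt_denominator:
            denom = np.sqrt(denom)
        re = np.abs(A.real) / denom[None, :]
        im = np.abs(A.imag) / denom[None, :]
        out[:, :, k] = (re * im) / (lam[:, None] ** 2)
    idx = np.arange(ch)
    out[idx, idx, :] = np.nan
    return GOPDCMap(values=out, freqs=spec.freqs)


def sliding_gopdc(rec: EEGRecording, win_s: float = 0.5,
                  step_s: float = 0.25, order: int | None = None,
                  max_order: int = 10,
                  freqs: np.ndarray | None = None,
                  **kwargs) -> tuple[list[GOPDCMap], np.ndarray]:
    """Time-varying gOPDC by refitting the MVAR on sliding windows.

    Returns one map per window plus the window-center times (seconds).
    """
    n_win = int(round(win_s * rec.rate))
    n_step = max(1, int(round(step_s * rec.rate)))
    if rec.n_samples < n_win:
        raise ValueError("recording shorter than one analysis window")
    maps: list[GOPDCMap] = []
    centers: list[float] = []
    for start in range(0, rec.n_samples - n_win + 1, n_step):
        seg = rec.data[:, start:start + n_win]
        m = order if order is not None else select_order(seg, max_order,
                                                         rate=rec.rate)
        model = fit_mvar(seg, m, rate=rec.rate)
        maps.append(gopdc(model, freqs, **kwargs))
        centers.append((start + n_win / 2.0) / rec.rate)
    return maps, np.asarray(centers)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def band_average(gmap: GOPDCMap,
                 bands: dict[str, tuple[float, float]] | None = None
                 ) -> dict[str, np.ndarray]:
    """Arithmetic mean of the map over the frequency bins inside each band."""
    if bands is None:
        bands = DEFAULT_BANDS
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        mask = (gmap.freqs >= lo) & (gmap.freqs <= hi)
        if not mask.any():
            raise ValueError(f"band {name} {lo}-{hi} Hz has no frequency bins")
        out[name] = gmap.values[:, :, mask].mean(axis=2)
    return out


def baseline_threshold(resting_maps: list[GOPDCMap] | list[np.ndarray],
                       percentile: float = 99.0) -> float:
    """Resting-state connectivity baseline: the given percentile over all
    finite off-diagonal values."""
    vals: list[np.ndarray] = []
    for m in resting_maps:
        arr = m.values if isinstance(m, GOPDCMap) else np.asarray(m)
        vals.append(arr[np.isfinite(arr)])
    pool = np.concatenate(vals)
    if pool.size == 0:
        raise ValueError("no finite values to threshold")
    return float(np.percentile(pool, percentile))


def apply_threshold(gmap: GOPDCMap | np.ndarray, thr: float) -> np.ndarray:
    """Retain only values strictly above the baseline; others set to 0."""
    arr = gmap.values if isinstance(gmap, GOPDCMap) else np.asarray(gmap)
    out = np.where(np.isfinite(arr) & (arr > thr), arr, 0.0)
    out = np.where(np.isfinite(arr), out, np.nan)
    return out


def normalize_map(matrix: np.ndarray) -> np.ndarray:
    """Scale a band matrix to max = 1 for reporting."""
    finite = matrix[np.isfinite(matrix)]
    peak = finite.max() if finite.size else 0.0
    return matrix / peak if peak > 0 else matrix
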