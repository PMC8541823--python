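"""Quantal analysis of spontaneous miniature postsynaptic potentials (mEPSPs).

Amplitude histograms of mEPSPs recorded at the larval neuromuscular junction
show peaks at integer multiples of a unitary ("quantal") amplitude q, because
each event releases an integer number of transmitter quanta.  The model fitted
here is the classical convolution of

* a binomial distribution B(n, p) for the quantal content i (number of quanta
  in an event), optionally truncated to i >= 1 since a spontaneous event
  contains at least one quantum, with
* a Gaussian for the amplitude of an i-quantum event, mean i*q and standard
  deviation sigma_i = i**peak_sd_exponent * sigma0.

``peak_sd_exponent`` is 0.5 under the standard assumption that quanta vary
independently (variances add), or 1.0 if the peak SD is taken to grow linearly
with quantal content.  Both conventions appear in the literature; the choice is
surfaced in every report.

The public surface is statsmodels-flavoured: build a
:class:`QuantalMixtureModel` from a histogram (or events) and call
:meth:`~QuantalMixtureModel.fit`, which returns a :class:`QuantalFitResult`
with parameter estimates, per-bin expected counts and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import binom

from .exceptions import DomainError, EmptyInputError, FitFailureError, ValidationError

__all__ = [
    "EventSeries",
    "AmplitudeHistogram",
    "QuantalParams",
    "QuantalMixtureModel",
    "QuantalFitResult",
    "build_histogram",
    "quantal_content_pmf",
    "peak_sd",
    "peak_density",
    "theoretical_distribution",
    "mepsp_frequency",
]

DEFAULT_BIN_WIDTH = 0.01  # mV


# ---------------------------------------------------------------------------
# containers


@dataclass
class EventSeries:
    """Amplitudes (mV) of mEPSP events from one cell, with optional times.

    Parameters
    ----------
    amplitudes : array-like of float
        Event amplitudes in mV, all strictly positive.
    duration : float, optional
        Recording duration in seconds (required for frequency).
    times : array-like of float, optional
        Event times in seconds, nondecreasing, within [0, duration].
    cell_id : str
        Label of the recorded cell.
    """

    amplitudes: np.ndarray
    duration: float | None = None
    times: np.ndarray | None = None
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1:
            raise ValidationError("amplitudes must be a 1-D list")
        if not np.all(np.isfinite(self.amplitudes)) or np.any(self.amplitudes <= 0):
            raise ValidationError("all amplitudes must be finite and > 0")
        if self.duration is not None and self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.amplitudes.shape:
                raise ValidationError("times and amplitudes must have equal length")
            if np.any(np.diff(self.times) < 0):
                raise ValidationError("times must be nondecreasing")
            if self.duration is not None and (
                np.any(self.times < 0) or np.any(self.times > self.duration)
            ):
                raise ValidationError("times must lie within [0, duration]")

    def __len__(self) -> int:
        return self.amplitudes.size


@dataclass
class AmplitudeHistogram:
    """Uniform-width amplitude histogram anchored at 0 mV.

    Bins are half-open ``[k*w, (k+1)*w)``; an amplitude exactly on an edge is
    counted in the right-hand bin.  Counts may be non-integer (expected-count
    pseudo-histograms are valid fit targets).
    """

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValidationError("need at least two bin edges")
        if self.counts.shape != (self.bin_edges.size - 1,):
            raise ValidationError("counts length must be n_edges - 1")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9, atol=0):
            raise ValidationError("bins must have uniform width")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_events(self) -> float:
        return float(self.counts.sum())


def build_histogram(
    events: EventSeries | Sequence[float] | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> AmplitudeHistogram:
    """Bin event amplitudes into 0-anchored half-open bins of width ``bin_width``.

    Trailing empty bins are trimmed (the last bin always contains the maximum
    amplitude); leading empty bins down to 0 are kept so that bin k always
    spans ``[k*w, (k+1)*w)``.
    """
    amps = events.amplitudes if isinstance(events, EventSeries) else np.asarray(events, float)
    if amps.size == 0:
        raise EmptyInputError("cannot build a histogram from zero events")
    if np.any(amps <= 0) or not np.all(np.isfinite(amps)):
        raise ValidationError("amplitudes must be finite and > 0")
    if not (bin_width > 0):
        raise ValidationError("bin_width must be > 0")
    n_bins = int(np.floor(amps.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    idx = np.minimum((amps / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return AmplitudeHistogram(bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# model primitives


@dataclass(frozen=True)
class QuantalParams:
    """Parameters of the binomial x Gaussian quantal release model.

    q : unitary (quantal) amplitude in mV
    sigma0 : SD of a single quantum in mV
    n : total number of releasable quanta
    p : release probability per quantum
    peak_sd_exponent : 0.5 (independent quanta, variances add) or 1.0
        (peak SD linear in quantal content)
    truncated : condition the binomial on i >= 1 (a spontaneous event contains
        at least one quantum)
    """

    q: float
    sigma0: float
    n: int
    p: float
    peak_sd_exponent: float = 0.5
    truncated: bool = True

    def __post_init__(self) -> None:
        if not (self.q > 0 and math.isfinite(self.q)):
            raise ValidationError("q must be finite and > 0")
        if not (self.sigma0 >= 0 and math.isfinite(self.sigma0)):
            raise ValidationError("sigma0 must be finite and >= 0")
        if int(self.n) != self.n or self.n < 1:
            raise ValidationError("n must be an integer >= 1")
        object.__setattr__(self, "n", int(self.n))
        if not (0 < self.p < 1):
            raise ValidationError("p must lie strictly between 0 and 1")
        if self.peak_sd_exponent not in (0.5, 1.0):
            raise ValidationError("peak_sd_exponent must be 0.5 or 1.0")


def quantal_content_pmf(model: QuantalParams, i: int) -> float:
    """P(quantal content = i) under the (optionally truncated) binomial.

    Untruncated: C(n,i) p^i (1-p)^(n-i).  Truncated: the same renormalised
    over i >= 1, with P(0) = 0.
    """
    if i < 0 or i > model.n:
        raise DomainError(f"quantal content i={i} outside [0, {model.n}]")
    raw = float(binom.pmf(i, model.n, model.p))
    if not model.truncated:
        return raw
    if i == 0:
        return 0.0
    p0 = float(binom.pmf(0, model.n, model.p))
    return raw / (1.0 - p0)


def peak_sd(model: QuantalParams, i: int) -> float:
    """SD of the i-quantum peak: ``i**peak_sd_exponent * sigma0``."""
    if i < 1:
        raise DomainError("peak index i must be >= 1")
    return float(i ** model.peak_sd_exponent * model.sigma0)


def peak_density(mu: float, sigma: float, y: float | np.ndarray) -> float | np.ndarray:
    """Gaussian probability density with mean ``mu`` and SD ``sigma`` at ``y``."""
    if not (sigma > 0):
        raise DomainError("sigma must be > 0")
    y = np.asarray(y, dtype=float)
    z = (y - mu) / sigma
    out = np.exp(-0.5 * z * z) / (math.sqrt(2.0 * math.pi) * sigma)
    return float(out) if out.ndim == 0 else out


@dataclass
class TheoreticalDistribution:
    """Expected per-bin counts of the quantal model over a histogram's bins."""

    expected_counts: np.ndarray
    mass_outside: float  # fraction of model mass beyond the histogram range
    warning: str | None = None

    @property
    def total(self) -> float:
        return float(self.expected_counts.sum())


def _peak_weights(model: QuantalParams) -> np.ndarray:
    """Truncation-aware pmf over i = 1..n (index 0 corresponds to i=1)."""
    i = np.arange(1, model.n + 1)
    w = binom.pmf(i, model.n, model.p)
    if model.truncated:
        w = w / (1.0 - binom.pmf(0, model.n, model.p))
    return w


def _expected_counts(
    model: QuantalParams, n_events: float, edges: np.ndarray
) -> tuple[np.ndarray, float]:
    """Expected counts per bin via Gaussian CDF differences (not midpoint
    density: the 0.01-mV bin width can be comparable to sigma_i)."""
    i = np.arange(1, model.n + 1)
    w = _peak_weights(model)
    mu = i * model.q
    sig = i.astype(float) ** model.peak_sd_exponent * model.sigma0
    if model.sigma0 == 0:
        # Degenerate peaks: all mass of peak i in the bin containing i*q.
        counts = np.zeros(edges.size - 1)
        outside = 0.0
        width = edges[1] - edges[0]
        for m, wi in zip(mu, w):
            # epsilon keeps an on-edge peak mean in the right-hand bin
            b = int(np.floor((m - edges[0]) / width + 1e-9))
            if 0 <= b < counts.size:
                counts[b] += wi
            else:
                outside += wi
        if not model.truncated:
            outside += float(binom.pmf(0, model.n, model.p)) if edges[0] > 0 else 0.0
        return n_events * counts, outside
    z = (edges[None, :] - mu[:, None]) / sig[:, None]
    cdf = ndtr(z)
    per_peak = np.diff(cdf, axis=1)  # (n_peaks, n_bins)
    counts = n_events * (w @ per_peak)
    inside_mass = float((w * (cdf[:, -1] - cdf[:, 0])).sum())
    untrunc_zero = 0.0
    if not model.truncated:
        # i = 0 events have zero amplitude; they fall in the first bin only if
        # the range starts at (or below) 0.
        p0 = float(binom.pmf(0, model.n, model.p))
        if edges[0] <= 0 <= edges[-1]:
            b = int(np.clip(np.searchsorted(edges, 0.0, side="right") - 1, 0, counts.size - 1))
            counts[b] += n_events * p0
            inside_mass += p0
        else:
            untrunc_zero = p0
    total_mass = 1.0
    outside = max(total_mass - inside_mass - untrunc_zero, 0.0) + untrunc_zero
    return counts, outside


def theoretical_distribution(
    model: QuantalParams, n_events: float, hist: AmplitudeHistogram
) -> TheoreticalDistribution:
    """Expected counts per histogram bin for ``n_events`` events.

    Peak i contributes ``n_events * pmf(i) * integral of N(i*q, sigma_i) over
    the bin``; the Gaussians of all peaks are pooled.  Mass falling outside the
    histogram range is reported, with a warning when it exceeds 1%.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    counts, outside = _expected_counts(model, float(n_events), hist.bin_edges)
    warning = None
    if outside > 0.01:
        warning = (
            f"histogram range excludes {outside:.1%} of the model mass; "
            "extend the range for a faithful comparison"
        )
    return TheoreticalDistribution(expected_counts=counts, mass_outside=outside, warning=warning)


def mepsp_frequency(events: EventSeries) -> float:
    """Mean event frequency in Hz: event count / recording duration."""
    if events.duration is None:
        raise ValidationError("EventSeries.duration is required to compute frequency")
    return len(events) / events.duration


# ---------------------------------------------------------------------------
# model fitting


def _initial_q(hist: AmplitudeHistogram) -> float:
    """Initial quantal size from the dominant spacing of histogram peaks.

    Uses the first positive local maximum of the autocorrelation of the
    (lightly smoothed, demeaned) counts; falls back to the mode amplitude for
    single-peak histograms.
    """
    c = hist.counts.astype(float)
    if c.size >= 7:
        kernel = np.array([1, 2, 3, 2, 1], dtype=float)
        kernel /= kernel.sum()
        c = np.convolve(c, kernel, mode="same")
    x = c - c.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    lag = None
    for k in range(2, ac.size - 1):
        if ac[k] > 0 and ac[k] >= ac[k - 1] and ac[k] > ac[k + 1]:
            lag = k
            break
    if lag is not None:
        return lag * hist.bin_width
    mode = int(np.argmax(hist.counts))
    return max(hist.centers[mode], hist.bin_width)


class QuantalMixtureModel:
    """Binomial x Gaussian mixture model for an mEPSP amplitude histogram.

    Parameters
    ----------
    hist : AmplitudeHistogram
        The fit target (typically 0.01-mV bins).
    peak_sd_exponent : {0.5, 1.0}
        Growth law of the peak SD with quantal content.
    truncated : bool
        Condition the binomial on i >= 1 (default).
    n_max : int
        Upper bound of the grid over the integer parameter n.
    objective : {"poisson", "lsq"}
        Poisson negative log-likelihood over bins (default; bin counts are
        Poisson-like and the objective is invariant to empty padding bins
        because out-of-range mass enters as a censored term), or least squares.
    min_events : int
        Minimum number of events required to attempt a fit.
    """

    def __init__(
        self,
        hist: AmplitudeHistogram,
        *,
        peak_sd_exponent: float = 0.5,
        truncated: bool = True,
        n_max: int = 10,
        objective: str = "poisson",
        min_events: int = 30,
    ) -> None:
        if objective not in ("poisson", "lsq"):
            raise ValidationError("objective must be 'poisson' or 'lsq'")
        if hist.n_events < min_events:
            raise ValidationError(
                f"histogram holds {hist.n_events:g} events; at least {min_events} required"
            )
        self.hist = hist
        self.peak_sd_exponent = float(peak_sd_exponent)
        self.truncated = bool(truncated)
        self.n_max = int(n_max)
        self.objective = objective
        self.min_events = int(min_events)

    @classmethod
    def from_events(
        cls, events: EventSeries, bin_width: float = DEFAULT_BIN_WIDTH, **kwargs
    ) -> "QuantalMixtureModel":
        return cls(build_histogram(events, bin_width), **kwargs)

    # -- objective ---------------------------------------------------------

    def _objective(self, q: float, sigma0: float, p: float, n: int) -> float:
        model = QuantalParams(
            q=q,
            sigma0=max(sigma0, 1e-9),
            n=n,
            p=p,
            peak_sd_exponent=self.peak_sd_exponent,
            truncated=self.truncated,
        )
        counts = self.hist.counts
        n_events = counts.sum()
        lam, _ = _expected_counts(model, n_events, self.hist.bin_edges)
        if self.objective == "lsq":
            return float(((lam - counts) ** 2).sum())
        lam = np.clip(lam, 1e-300, None)
        # Total expected mass over bins + censored out-of-range term is
        # n_events by construction, so the NLL reduces to a constant minus the
        # count-weighted log term; this makes the fit invariant to padding the
        # histogram with empty bins.
        return float(n_events - (counts * np.log(lam)).sum())

    def fit(self, *, seed: int = 0, n_starts: int = 3) -> "QuantalFitResult":
        """Fit (q, sigma0, p) by bounded multi-start local optimisation inside
        an exhaustive grid over n; ties in the objective favour smaller n.
        """
        rng = np.random.default_rng(seed)
        hist = self.hist
        span = float(hist.bin_edges[-1])
        q0 = min(_initial_q(hist), span)
        bounds = [
            (hist.bin_width, span),
            (1e-6, span / 2.0),
            (1e-4, 1.0 - 1e-4),
        ]
        base_starts = [
            (q0, 0.15 * q0, 0.3),
            (q0, 0.08 * q0, 0.6),
            (q0, 0.30 * q0, 0.45),
        ]
        best: tuple[float, int, np.ndarray, bool] | None = None
        for n in range(1, self.n_max + 1):
            for s in range(n_starts):
                q_s, s_s, p_s = base_starts[s % len(base_starts)]
                if s >= len(base_starts):
                    q_s *= 1.0 + 0.1 * rng.standard_normal()
                    s_s *= math.exp(0.3 * rng.standard_normal())
                    p_s = float(np.clip(p_s + 0.2 * rng.standard_normal(), 0.05, 0.95))
                x0 = np.clip(
                    [q_s, s_s, p_s],
                    [b[0] for b in bounds],
                    [b[1] for b in bounds],
                )
                try:
                    res = minimize(
                        lambda x: self._objective(x[0], x[1], x[2], n),
                        x0,
                        method="L-BFGS-B",
                        bounds=bounds,
                    )
                except (ValueError, FloatingPointError):  # pragma: no cover
                    continue
                if not np.isfinite(res.fun):
                    continue
                # strict improvement threshold: equal objectives keep smaller n
                if best is None or res.fun < best[0] - 1e-9:
                    best = (float(res.fun), n, res.x.copy(), bool(res.success))
        if best is None:
            raise FitFailureError(
                "no optimisation start produced a finite objective; "
                "check histogram content and model configuration"
            )
        obj, n_best, x, converged = best
        params = QuantalParams(
            q=float(x[0]),
            sigma0=float(x[1]),
            n=n_best,
            p=float(x[2]),
            peak_sd_exponent=self.peak_sd_exponent,
            truncated=self.truncated,
        )
        theo = theoretical_distribution(params, hist.n_events, hist)
        return QuantalFitResult(
            model=self,
            params=params,
            n_events=hist.n_events,
            objective=obj,
            expected_counts=theo.expected_counts,
            mass_outside=theo.mass_outside,
            status="converged" if converged else "not_converged",
            warning=theo.warning,
        )


@dataclass
class QuantalFitResult:
    """Estimates and diagnostics from :meth:`QuantalMixtureModel.fit`."""

    model: QuantalMixtureModel
    params: QuantalParams
    n_events: float
    objective: float
    expected_counts: np.ndarray
    mass_outside: float
    status: str
    warning: str | None = None

    @property
    def quantal_size(self) -> float:
        """The estimated unitary amplitude q in mV."""
        return self.params.q

    def predict(self) -> np.ndarray:
        """Expected counts per histogram bin under the fitted parameters."""
        return self.expected_counts

    def summary(self) -> str:
        p = self.params
        lines = [
            "Quantal mixture model fit",
            "=" * 41,
            f"{'events fitted':<28}{self.n_events:>13g}",
            f"{'quantal size q (mV)':<28}{p.q:>13.4f}",
            f"{'sigma0 (mV)':<28}{p.sigma0:>13.4f}",
            f"{'releasable quanta n':<28}{p.n:>13d}",
            f"{'release probability p':<28}{p.p:>13.4f}",
            f"{'peak SD exponent':<28}{p.peak_sd_exponent:>13.1f}",
            f"{'binomial truncated (i>=1)':<28}{str(p.truncated):>13}",
            f"{'objective':<28}{self.model.objective:>13}",
            f"{'objective value':<28}{self.objective:>13.4f}",
            f"{'mass outside range':<28}{self.mass_outside:>13.2e}",
            f"{'status':<28}{self.status:>13}",
        ]
        if self.warning:
            lines.append(f"warning: {self.warning}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram with the fitted theoretical distribution superimposed."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.model.hist
        ax.bar(h.centers, h.counts, width=h.bin_width, color="0.7", label="observed")
        ax.plot(h.centers, self.expected_counts, "k-", lw=1.5, label="model")
        ax.set_xlabel("mEPSP amplitude (mV)")
        ax.set_ylabel("events per bin")
        ax.legend(frameon=False)
        ax.set_title(f"q = {self.quantal_size:.3f} mV")
        return ax
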