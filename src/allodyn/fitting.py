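"""Functional-assay models: glycosylase kinetics, binding, mutation frequency.

The glycosylase follows a minimal kinetic scheme

    E + S  <=>(k1, k-1)  E.S  ->(k2)  E.P  ->(k3)  E + P

with fast binding pre-equilibrium, so only the chemistry rate k2 and the
product-release (turnover) rate k3 are estimated; k1 and k-1 are
documented symbols, never fit.

* Single turnover (STO, [E] > [S]): P(t) = A0 (1 - exp(-k2 t)).
* Multiple turnover (MTO, [E] < [S]): burst-plus-linear
  P(t) = A0 (1 - exp(-k2 t)) + A0 k3 t, where the burst amplitude A0
  measures the catalytically active enzyme; active fraction =
  A0 / [E]_total.
* One-site specific binding: Y = Bmax X / (KD + X), Y in percent bound.
* Mutation frequency from a rifampicin-resistance fluctuation assay:
  f = median(resistant counts) / mean(viable counts), compared across
  variants as fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from allodyn.errors import FitError, IntegrityError

logger = logging.getLogger(__name__)


@dataclass
class GlycosylaseDataset:
    """Time course(s) of product formation.

    ``time_min`` and ``product_nM`` are flat arrays; ``replicate``
    groups points into repeats of the same schedule.  Concentrations in
    nM; ``condition`` is "STO" ([E] > [S]) or "MTO" ([E] < [S]).
    """

    time_min: np.ndarray
    product_nM: np.ndarray
    enzyme_nM: float
    substrate_nM: float
    condition: str
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.product_nM = np.asarray(self.product_nM, dtype=float)
        if self.condition not in ("STO", "MTO"):
            raise IntegrityError(f"condition must be STO or MTO, got {self.condition!r}")
        if self.time_min.shape != self.product_nM.shape:
            raise IntegrityError("time and product arrays differ in length")
        if np.any(self.time_min < 0):
            raise IntegrityError("negative time points")
        if self.replicate is None:
            self.replicate = np.zeros_like(self.time_min, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)
        for rep in np.unique(self.replicate):
            t = self.time_min[self.replicate == rep]
            if np.any(np.diff(t) <= 0):
                raise IntegrityError(
                    f"replicate {rep}: times must be strictly increasing"
                )
        if np.any(self.product_nM > self.substrate_nM * (1 + 1e-9)):
            raise IntegrityError("product exceeds substrate concentration")


@dataclass
class KineticFit:
    """Estimated Scheme parameters.

    k2 and k3 in min^-1, amplitude A0 in nM.  ``active_fraction`` =
    A0 / [E]_total (MTO only).  The binding steps k1/k-1 of the scheme
    are assumed at fast pre-equilibrium and are not estimated.
    """

    condition: str
    k2: float
    a0: float
    k3: float | None = None
    active_fraction: float | None = None
    stderr: dict = field(default_factory=dict)
    rss: float = 0.0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.k2 > 0:
            raise IntegrityError("k2 must be positive")
        if not self.a0 > 0:
            raise IntegrityError("amplitude must be positive")


@dataclass
class BindingFit:
    """One-site binding parameters: KD (units of X), Bmax (%)."""

    kd: float
    bmax: float
    stderr: dict = field(default_factory=dict)
    upper_limit: bool = False
    kd_upper_bound: float | None = None

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise IntegrityError("KD must be positive")
        if not 0 < self.bmax <= 110:
            raise IntegrityError("Bmax must lie in (0, 110] percent")


@dataclass
class MutFreqResult:
    """Mutation frequency f = median(resistant) / mean(viable)."""

    f: float
    n_resistant: int
    n_viable: int

    def __post_init__(self) -> None:
        if self.f < 0:
            raise IntegrityError("mutation frequency must be >= 0")


# ---------------------------------------------------------------------------
# model curves
# ---------------------------------------------------------------------------

def sto_curve(t: np.ndarray, a0: float, k2: float) -> np.ndarray:
    return a0 * (1.0 - np.exp(-k2 * t))


def mto_curve(t: np.ndarray, a0: float, k2: float, k3: float) -> np.ndarray:
    return a0 * (1.0 - np.exp(-k2 * t)) + a0 * k3 * t


def binding_curve(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    return bmax * x / (kd + x)


def _weights(dataset: GlycosylaseDataset) -> np.ndarray | None:
    """Per-point replicate SD when >= 3 replicates, else unweighted."""
    reps = np.unique(dataset.replicate)
    if len(reps) < 3:
        return None
    # SD of replicate values at each time point, mapped back to points
    sd_by_t: dict[float, float] = {}
    for t in np.unique(dataset.time_min):
        vals = dataset.product_nM[dataset.time_min == t]
        if len(vals) >= 3:
            sd_by_t[t] = float(np.std(vals, ddof=1))
    if not sd_by_t:
        return None
    floor = max(1e-6, 0.1 * np.median([s for s in sd_by_t.values() if s > 0] or [1e-6]))
    return np.array([max(sd_by_t.get(t, floor), floor) for t in dataset.time_min])


def _run_fit(func, x, y, p0, bounds, sigma=None, names=()):
    try:
        popt, pcov = curve_fit(
            func, x, y, p0=p0, bounds=bounds, sigma=sigma,
            absolute_sigma=False, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"fit failed to converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    resid = y - func(x, *popt)
    return popt, dict(zip(names, perr)), float((resid**2).sum())


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def fit_sto(dataset: GlycosylaseDataset) -> KineticFit:
    """Fit the single-turnover exponential P(t) = A0 (1 - e^{-k2 t})."""
    if dataset.condition != "STO":
        raise FitError("fit_sto requires an STO dataset")
    if len(np.unique(dataset.time_min)) < 4:
        raise FitError("STO fit needs >= 4 distinct time points")
    t, p = dataset.time_min, dataset.product_nM
    a0_guess = max(p.max(), 1e-6)
    pos = t[p > 0.5 * a0_guess]
    k2_guess = np.log(2) / max(pos.min(), 1e-3) if pos.size else 1.0
    popt, stderr, rss = _run_fit(
        sto_curve, t, p, p0=[a0_guess, k2_guess],
        bounds=([1e-12, 1e-9], [dataset.substrate_nM * 1.001, np.inf]),
        sigma=_weights(dataset), names=("a0", "k2"),
    )
    a0, k2 = popt
    flags = []
    if a0 > dataset.substrate_nM * 0.999 and abs(a0 - dataset.substrate_nM * 1.001) < 1e-9:
        flags.append("amplitude_at_bound")
    if k2 < 1e-8:
        flags.append("k2_at_bound")
    return KineticFit(condition="STO", k2=float(k2), a0=float(a0),
                      stderr=stderr, rss=rss, flags=tuple(flags))


def fit_mto(dataset: GlycosylaseDataset) -> KineticFit:
    """Fit the burst equation P(t) = A0 (1 - e^{-k2 t}) + A0 k3 t.

    The amplitude A0 estimates the active-enzyme concentration;
    active_fraction = A0 / [E]_total.  A fit in which burst and linear
    phases are statistically indistinguishable is flagged
    ``degenerate``; A0 > [E]_total triggers a warning flag.
    """
    if dataset.condition != "MTO":
        raise FitError("fit_mto requires an MTO dataset")
    t, p = dataset.time_min, dataset.product_nM
    if len(np.unique(t)) < 5:
        raise FitError("MTO fit needs >= 5 distinct time points")
    # initialization: A0 from the early-time plateau, k3 from terminal slope
    t_sorted = np.sort(np.unique(t))
    mid = t_sorted[len(t_sorted) // 3]
    a0_guess = max(float(np.mean(p[t <= mid])) if np.any(t <= mid) else p.max() / 4, 1e-3)
    late = t >= t_sorted[max(len(t_sorted) - 3, 0)]
    if late.sum() >= 2 and np.ptp(t[late]) > 0:
        slope = np.polyfit(t[late], p[late], 1)[0]
    else:
        slope = 0.0
    k3_guess = max(slope / a0_guess, 1e-3)
    popt, stderr, rss = _run_fit(
        mto_curve, t, p, p0=[a0_guess, 1.0, k3_guess],
        bounds=([1e-12, 1e-9, 1e-12], [dataset.substrate_nM * 1.001, np.inf, np.inf]),
        sigma=_weights(dataset), names=("a0", "k2", "k3"),
    )
    a0, k2, k3 = (float(v) for v in popt)
    flags = []
    if a0 > dataset.enzyme_nM:
        flags.append("amplitude_exceeds_enzyme")
        logger.warning("MTO amplitude %.3g nM exceeds [E]=%.3g nM",
                       a0, dataset.enzyme_nM)
    # burst indistinguishable from linear: exponential saturates slower
    # than the sampled range or amplitude error swamps the estimate
    if k2 * t_sorted[-1] < 1.0 or (
        stderr.get("a0", 0.0) > 0 and stderr["a0"] > a0
    ):
        flags.append("degenerate")
    return KineticFit(
        condition="MTO", k2=k2, a0=a0, k3=k3,
        active_fraction=min(a0 / dataset.enzyme_nM, 1.0) if dataset.enzyme_nM > 0 else None,
        stderr=stderr, rss=rss, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# binding
# ---------------------------------------------------------------------------

def fit_binding(x, y) -> BindingFit:
    """Fit the one-site isotherm Y = Bmax X / (KD + X).

    X: concentrations (any consistent unit), Y: percent bound.  When the
    isotherm is already saturated at the smallest nonzero concentration
    (Y >= 0.9 Bmax there) the fit only bounds KD from above; the result
    is flagged ``upper_limit`` with ``kd_upper_bound`` set to that
    concentration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if np.ptp(y) < 1e-12:
        raise FitError("all Y values identical; binding fit undefined")
    nonzero = x[x > 0]
    if nonzero.size == 0:
        raise FitError("no nonzero concentrations")
    if len(np.unique(x)) < 5:
        logger.warning("binding fit with < 5 concentrations; KD poorly "
                       "constrained")
    bmax_guess = max(y.max(), 1.0)
    half = np.abs(y - bmax_guess / 2)
    kd_guess = max(float(x[np.argmin(half)]), nonzero.min() / 10)
    popt, stderr, _ = _run_fit(
        binding_curve, x, y, p0=[bmax_guess, kd_guess],
        bounds=([1e-9, 1e-15], [110.0, np.inf]), names=("bmax", "kd"),
    )
    bmax, kd = (float(v) for v in popt)
    x_min = float(nonzero.min())
    y_at_min = float(np.mean(y[x == x_min]))
    upper = y_at_min >= 0.9 * bmax
    if upper:
        logger.info("isotherm saturated at X=%.3g; KD reported as an upper "
                    "limit", x_min)
    return BindingFit(
        kd=min(kd, x_min) if upper else kd,
        bmax=bmax, stderr=stderr,
        upper_limit=upper, kd_upper_bound=x_min if upper else None,
    )


# ---------------------------------------------------------------------------
# mutation frequency
# ---------------------------------------------------------------------------

def mutation_frequency(resistant_counts, viable_counts) -> MutFreqResult:
    """f = median(resistant colonies) / mean(viable colonies)."""
    res = np.asarray(resistant_counts, dtype=float)
    via = np.asarray(viable_counts, dtype=float)
    if res.size == 0 or via.size == 0:
        raise IntegrityError("need at least one count in each list")
    mean_viable = float(via.mean())
    if mean_viable == 0:
        raise FitError("mean viable count is zero; f undefined")
    return MutFreqResult(
        f=float(np.median(res)) / mean_viable,
        n_resistant=int(res.size),
        n_viable=int(via.size),
    )


def fold_change(result, reference) -> float:
    """Ratio of a value (or MutFreqResult) to a positive reference."""
    val = result.f if isinstance(result, MutFreqResult) else float(result)
    ref = reference.f if isinstance(reference, MutFreqResult) else float(reference)
    if not ref > 0:
        raise FitError("fold change undefined for non-positive reference")
    return val / ref
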