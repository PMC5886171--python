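"""Monomer–dimer assembly analysis in solution.

Three experimental readouts are supported:

* size-exclusion chromatograms — species quantified as peak-area fractions
  of the total over labeled elution-volume windows;
* dynamic light scattering — the measured hydrodynamic radius R_H maps
  linearly onto dimer fraction between the monomer (2.0 nm) and dimer
  (3.0 nm) reference radii;
* time courses — the monomer→dimer transition is fit with pseudo-first-order
  relaxation kinetics, f(t) = f_inf − (f_inf − f0)·exp(−k·t).

The concentration dependence of the equilibrium follows mass action for
2M ⇌ D with Kd = [M]²/[D] and conservation [M] + 2[D] = C_total (monomer
equivalents); the dimer mass fraction 2[D]/C_total has a closed form used
both for fitting Kd and as the model curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Chromatogram",
    "SpeciesFractions",
    "DlsCalibration",
    "KineticsFit",
    "EquilibriumModel",
    "integrate_peaks",
    "calibrate_dls",
    "first_order_curve",
    "fit_first_order",
    "equilibrium_fraction",
    "fit_kd",
    "MONOMER_RH_NM",
    "DIMER_RH_NM",
    "G2_MONOMER_KDA",
]

#: reference hydrodynamic radii for the G2 monomer and dimer (nm)
MONOMER_RH_NM = 2.0
DIMER_RH_NM = 3.0
#: default monomer molecular weight for mg/ml → molar conversion (kDa)
G2_MONOMER_KDA = 13.0


@dataclass
class Chromatogram:
    """Elution profile: volume grid (ml, increasing) vs detector signal."""

    volume_ml: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.volume_ml.shape != self.signal.shape or self.volume_ml.ndim != 1:
            raise ValueError("volume and signal must be equal-length 1-D arrays")
        if not np.all(np.diff(self.volume_ml) > 0):
            raise ValueError("elution volume grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")


@dataclass
class SpeciesFractions:
    fractions: dict[str, float]
    areas: dict[str, float]
    windows: dict[str, tuple[float, float]]

    def __getitem__(self, label: str) -> float:
        return self.fractions[label]


def integrate_peaks(
    chrom: Chromatogram,
    windows: dict[str, tuple[float, float]],
    baseline: bool = True,
) -> SpeciesFractions:
    """Peak areas per labeled window as fractions of the total over all windows.

    Trapezoidal integration; by default a straight baseline through the
    signal at each window's endpoints is subtracted first.
    """
    items = sorted(windows.items(), key=lambda kv: kv[1][0])
    for (la, (a0, a1)), (lb, (b0, b1)) in zip(items, items[1:]):
        if b0 < a1:
            raise ValueError(f"windows {la!r} and {lb!r} overlap")
    v, s = chrom.volume_ml, chrom.signal
    if any(w[0] < v[0] or w[1] > v[-1] for w in windows.values()):
        raise ValueError("window outside the elution grid")
    areas: dict[str, float] = {}
    for label, (lo, hi) in windows.items():
        mask = (v >= lo) & (v <= hi)
        vv, ss = v[mask], s[mask]
        if len(vv) < 2:
            raise ValueError(f"window {label!r} covers fewer than 2 grid points")
        if baseline:
            base = ss[0] + (ss[-1] - ss[0]) * (vv - vv[0]) / (vv[-1] - vv[0])
            ss = ss - base
        areas[label] = float(np.trapezoid(ss, vv))
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("zero total area over the integration windows")
    return SpeciesFractions(
        fractions={k: a / total for k, a in areas.items()},
        areas=areas,
        windows=dict(windows),
    )


@dataclass(frozen=True)
class DlsCalibration:
    """Linear R_H → dimer-fraction calibration anchored at the two references."""

    r_h_monomer: float = MONOMER_RH_NM
    r_h_dimer: float = DIMER_RH_NM
    sd_nm: float = 0.3  # stated uncertainty on both reference radii

    def __post_init__(self) -> None:
        if not (self.r_h_dimer > self.r_h_monomer > 0):
            raise ValueError("require R_H(dimer) > R_H(monomer) > 0")

    def fraction(self, r_h: float | np.ndarray) -> float | np.ndarray:
        return calibrate_dls(r_h, self)

    def radius(self, fraction: float | np.ndarray) -> float | np.ndarray:
        """Inverse map: dimer fraction → hydrodynamic radius (nm)."""
        return self.r_h_monomer + np.asarray(fraction) * (self.r_h_dimer - self.r_h_monomer)


def calibrate_dls(r_h, cal: DlsCalibration | None = None):
    """Dimer fraction from a hydrodynamic radius via the linear calibration.

    Readings outside [monomer, dimer] are clamped to [0, 1]; values beyond
    three reference standard deviations trigger a warning but still clamp.
    """
    cal = cal or DlsCalibration()
    r = np.asarray(r_h, dtype=float)
    lo = cal.r_h_monomer - 3 * cal.sd_nm
    hi = cal.r_h_dimer + 3 * cal.sd_nm
    if np.any(r < lo) or np.any(r > hi):
        warnings.warn("R_H reading beyond 3 s.d. of the calibration references")
    frac = (r - cal.r_h_monomer) / (cal.r_h_dimer - cal.r_h_monomer)
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if np.isscalar(r_h) else out


def first_order_curve(t, k: float, f0: float, f_inf: float):
    """Pseudo-first-order relaxation: f(t) = f_inf − (f_inf − f0)·exp(−k·t)."""
    return f_inf - (f_inf - f0) * np.exp(-k * np.asarray(t, dtype=float))


@dataclass
class KineticsFit:
    k: float  # rate constant, 1/h
    f0: float  # dimer fraction at t = 0
    f_inf: float  # plateau dimer fraction
    k_se: float
    f0_se: float
    f_inf_se: float
    residuals: np.ndarray
    k_at_bound: bool = False

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    def to_dict(self) -> dict:
        return {
            "k_per_h": self.k,
            "k_se": self.k_se,
            "f0": self.f0,
            "f0_se": self.f0_se,
            "f_inf": self.f_inf,
            "f_inf_se": self.f_inf_se,
            "rss": self.rss,
            "k_at_bound": self.k_at_bound,
        }


def _initial_k(t: np.ndarray, f: np.ndarray) -> float:
    # log-linear transform of the early approach to the apparent plateau
    f_inf = f[-1] if f[-1] > f[0] else max(f.max(), f[0] + 1e-3)
    span = f_inf - f[0]
    if span <= 0:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(np.clip((f_inf - f) / span, 1e-12, None))
    good = (f < f_inf - 0.05 * span) & (t > 0)
    if good.sum() >= 2:
        slope = np.polyfit(t[good], y[good], 1)[0]
        if slope < 0:
            return float(-slope)
    return 1.0


def fit_first_order(t, f) -> KineticsFit:
    """Least-squares fit of the pseudo-first-order model to a dimer-fraction series.

    ``t`` in hours, ``f`` in [0, 1].  Initialisation: k from a log-linear
    transform of the early points, f_inf from the final observation.  A rate
    pinned at the k ≥ 0 bound is flagged rather than silently reported.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("t and f must be equal-length 1-D arrays")
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if np.any((f < -1e-9) | (f > 1 + 1e-9)):
        raise ValueError("dimer fractions must lie in [0, 1]")

    p0 = (_initial_k(t, f), float(np.clip(f[0], 0, 1)), float(np.clip(f[-1], 0, 1)))
    tried = [p0]
    bounds = ([0.0, 0.0, 0.0], [np.inf, 1.0, 1.0])
    last_exc: Exception | None = None
    for trial in (p0, (1.0, 0.0, 0.5), (0.1, 0.0, 1.0), (10.0, 0.0, 1.0)):
        tried.append(trial)
        try:
            popt, pcov = curve_fit(
                first_order_curve, t, f, p0=trial, bounds=bounds, maxfev=10000
            )
            break
        except RuntimeError as exc:
            last_exc = exc
    else:
        raise RuntimeError(f"kinetics fit failed to converge (initialisations tried: {tried})") from last_exc

    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    res = f - first_order_curve(t, *popt)
    return KineticsFit(
        k=float(popt[0]),
        f0=float(popt[1]),
        f_inf=float(popt[2]),
        k_se=float(se[0]),
        f0_se=float(se[1]),
        f_inf_se=float(se[2]),
        residuals=res,
        k_at_bound=bool(popt[0] < 1e-9),
    )


# ---------------------------------------------------------------------------
# Mass-action 2M ⇌ D equilibrium
# ---------------------------------------------------------------------------

def equilibrium_fraction(c_total, kd: float):
    """Dimer mass fraction 2[D]/C at equilibrium for 2M ⇌ D.

    Solves Kd = [M]²/[D] with [M] + 2[D] = C_total in closed form:
    4D² − (4C + Kd)·D + C² = 0, taking the physical root.  At C_total = Kd
    the fraction is exactly 1/2; it vanishes in the dilution limit.
    """
    c = np.asarray(c_total, dtype=float)
    if np.any(c <= 0) or kd <= 0:
        raise ValueError("c_total and Kd must be positive")
    b = 4.0 * c + kd
    dimer = (b - np.sqrt(b * b - 16.0 * c * c)) / 8.0
    frac = 2.0 * dimer / c
    return float(frac) if np.isscalar(c_total) else frac


@dataclass
class EquilibriumModel:
    kd: float  # molar (monomer² / dimer)
    kd_se: float
    points: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, c_total):
        return equilibrium_fraction(c_total, self.kd)

    def to_dict(self) -> dict:
        return {"Kd_molar": self.kd, "Kd_se": self.kd_se, "n_points": len(self.points)}


def fit_kd(points) -> EquilibriumModel:
    """Least-squares Kd from (total concentration, dimer mass fraction) pairs.

    Requires ≥3 points spanning more than a 2-fold concentration range.
    Dimer fraction must (noisily) increase with concentration for the
    mass-action model to make sense; clear non-monotonicity only warns,
    because scatter at low fractions is common.
    """
    pts = [(float(c), float(f)) for c, f in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 concentration points")
    c = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if c.max() / c.min() <= 2.0:
        raise ValueError("concentration series must span more than a 2-fold range")
    if np.all(f == 0):
        raise ValueError("all-zero dimer fractions: Kd unidentifiable")
    order = np.argsort(c)
    df = np.diff(f[order])
    if np.any(df < -0.15):
        warnings.warn("dimer fraction decreases with concentration beyond noise tolerance")

    # fit in log-space to keep Kd positive and well-scaled
    def model(cc, log_kd):
        return equilibrium_fraction(cc, float(np.exp(log_kd)))

    guesses = np.log(np.array([c.min(), np.median(c), c.max(), 10 * c.max()]))
    best = None
    for g in guesses:
        try:
            popt, pcov = curve_fit(model, c, f, p0=[g], maxfev=10000)
        except RuntimeError:
            continue
        rss = float(np.sum((f - model(c, popt[0])) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError("Kd fit failed to converge")
    popt, pcov, _ = best
    kd = float(np.exp(popt[0]))
    kd_se = float(kd * np.sqrt(max(pcov[0, 0], 0.0)))  # delta method on log-Kd
    return EquilibriumModel(kd=kd, kd_se=kd_se, points=pts)
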