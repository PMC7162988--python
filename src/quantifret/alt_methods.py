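"""Rival gamma/beta calibrations and the method-comparison harness.

Two earlier sensitized-emission calibrations are mathematically equivalent
to the plane-fit factors (gamma_M, beta_X):

* Lee-style: compute E_raw and S_raw with crosstalk corrections only
  (gamma = beta = 1), then fit the linear relation 1/S_raw = Omega +
  Sigma * E_raw assuming 1:1 stoichiometry.  The line parameters map to
  the factors through Omega = 1 + beta*gamma and Sigma = beta*(1 - gamma),
  i.e. beta = Omega + Sigma - 1 and gamma = (Omega - 1)/beta.  Its known
  weakness is the divergence of 1/S for small S.
* Chen-style two-step (G, k): G (= gamma_M) from two constructs with
  well-separated FRET efficiencies, then k from a known-stoichiometry
  standard, with beta_X = 1/(G*k).  Its weakness is that the uncertainty
  of G grows as the FRET separation of the two standards shrinks.

On noise-free data all three routes must agree exactly with the
generating instrument; the comparison harness quantifies their relative
robustness under noise (bootstrap dispersion, reduced FRET range).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CollinearityError, fit_plane

__all__ = [
    "MethodResult",
    "lee_calibration",
    "chen_calibration",
    "quanti_calibration",
    "compare_methods",
    "reduced_range_test",
    "relative_variation",
    "method_bootstrap_sd",
]

PixelSet = tuple[np.ndarray, np.ndarray, np.ndarray]  # (I_DD, I_DA_corr, I_AA)


@dataclass
class MethodResult:
    """A calibration method's factors mapped onto (gamma_M, beta_X)."""

    method: str
    gamma_like: float
    beta_like: float
    e_medians: dict[str, float] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


def _as_pixels(dd, c, aa) -> PixelSet:
    dd = np.ravel(np.asarray(dd, dtype=float))
    c = np.ravel(np.asarray(c, dtype=float))
    aa = np.ravel(np.asarray(aa, dtype=float))
    ok = np.isfinite(dd) & np.isfinite(c) & np.isfinite(aa)
    return dd[ok], c[ok], aa[ok]


def quanti_calibration(dd, c, aa, s0: float = 0.5) -> MethodResult:
    """Single-step plane fit, wrapped in the comparison interface."""
    fit = fit_plane(dd, c, aa, s0=s0)
    return MethodResult(
        method="quanti", gamma_like=fit.gamma_M, beta_like=fit.beta_X,
        diagnostics={"r_squared": fit.r_squared, "n_pixels": fit.n_pixels},
    )


def lee_calibration(
    dd, c, aa, s_floor: float = 0.05, e_spread_min: float = 1e-6,
) -> MethodResult:
    """Linear 1/S_raw-vs-E_raw calibration assuming 1:1 stoichiometry.

    ``c`` is the crosstalk-corrected sensitized emission.  Pixels with
    S_raw below ``s_floor`` are excluded (1/S diverges there) and
    reported in the diagnostics.
    """
    dd, c, aa = _as_pixels(dd, c, aa)
    q = dd + c                    # uncorrected total donor signal
    tot = q + aa
    with np.errstate(invalid="ignore", divide="ignore"):
        e_raw = np.where(q != 0, c / np.where(q != 0, q, 1.0), np.nan)
        s_raw = np.where(tot > 0, q / np.where(tot > 0, tot, 1.0), np.nan)
    ok = np.isfinite(e_raw) & np.isfinite(s_raw) & (s_raw > s_floor)
    n_excluded = int(np.size(s_raw) - np.count_nonzero(ok))
    e_raw, s_raw = e_raw[ok], s_raw[ok]
    if e_raw.size < 2 or np.ptp(e_raw) < e_spread_min:
        raise ValueError(
            "Lee calibration is degenerate: the dataset spans a single "
            "FRET level, the slope of 1/S vs E is unidentifiable"
        )
    slope, intercept = np.polyfit(e_raw, 1.0 / s_raw, 1)
    beta = intercept + slope - 1.0
    if beta <= 0:
        raise ValueError(f"Lee inversion gave non-positive beta = {beta:.4g}")
    gamma = (intercept - 1.0) / beta
    if gamma <= 0:
        raise ValueError(f"Lee inversion gave non-positive gamma = {gamma:.4g}")
    return MethodResult(
        method="lee", gamma_like=float(gamma), beta_like=float(beta),
        diagnostics={
            "intercept": float(intercept), "slope": float(slope),
            "n_pixels": int(e_raw.size), "n_excluded_low_s": n_excluded,
        },
    )


def chen_calibration(
    population_1: PixelSet,
    population_2: PixelSet,
    standard: PixelSet,
    s0: float = 0.5,
    separation_warn: float = 0.05,
) -> MethodResult:
    """Two-step (G, k) calibration.

    Step 1 determines G from the constraint that, for two constructs with
    the same stoichiometry, the gamma-corrected total-donor to acceptor
    ratio (G*I_DD + I_DA_corr)/I_AA is construct-independent; with
    per-pixel ratio means m_d = <I_DD/I_AA> and m_c = <I_DA_corr/I_AA>,

        G = (m_c2 - m_c1) / (m_d1 - m_d2).

    Step 2 measures that ratio on a known-stoichiometry standard to get
    beta = (S0/(1-S0)) / median_ratio and k = 1/(G*beta).  Warns when the
    two populations' apparent FRET separation is below
    ``separation_warn`` (absolute): the estimate then degrades rapidly.
    """
    dd1, c1, aa1 = _as_pixels(*population_1)
    dd2, c2, aa2 = _as_pixels(*population_2)
    for name, (dd, aa) in (("population_1", (dd1, aa1)),
                           ("population_2", (dd2, aa2))):
        if dd.size == 0:
            raise ValueError(f"{name} has no usable pixels")
    m_d1, m_c1 = np.mean(dd1 / aa1), np.mean(c1 / aa1)
    m_d2, m_c2 = np.mean(dd2 / aa2), np.mean(c2 / aa2)
    denom = m_d1 - m_d2
    if denom == 0:
        raise ZeroDivisionError(
            "the two populations have identical mean intensity ratios; "
            "G is undetermined"
        )
    g = (m_c2 - m_c1) / denom
    if g <= 0:
        raise ValueError(f"Chen step 1 gave non-positive G = {g:.4g}")

    e1 = float(np.median(c1 / (g * dd1 + c1)))
    e2 = float(np.median(c2 / (g * dd2 + c2)))
    if abs(e1 - e2) < separation_warn:
        warnings.warn(
            f"FRET separation of the two standards is only "
            f"{abs(e1 - e2):.3f}; the uncertainty of G grows as the FRET "
            "distance decreases", stacklevel=2,
        )

    dds, cs, aas = _as_pixels(*standard)
    ratio = np.median((g * dds + cs) / aas)
    if ratio <= 0:
        raise ValueError("Chen step 2: non-positive median intensity ratio")
    beta = (s0 / (1.0 - s0)) / float(ratio)
    k = 1.0 / (g * beta)
    return MethodResult(
        method="chen", gamma_like=float(g), beta_like=float(beta),
        diagnostics={"G": float(g), "k": float(k),
                     "e_separation": abs(e1 - e2),
                     "n_pixels_standard": int(dds.size)},
    )


def _e_medians(populations: dict[str, PixelSet], gamma: float) -> dict[str, float]:
    out = {}
    for name, (dd, c, aa) in populations.items():
        dd, c, aa = _as_pixels(dd, c, aa)
        q = gamma * dd + c
        ok = q > 0
        out[name] = float(np.median(c[ok] / q[ok]))
    return out


def compare_methods(
    populations: dict[str, PixelSet],
    s0: float = 0.5,
    truth=None,
) -> pd.DataFrame:
    """Run all three calibrations on one dataset and tabulate the results.

    ``populations`` maps construct name to (I_DD, I_DA_corr, I_AA) pixel
    arrays.  Chen's method uses the two populations with the most extreme
    apparent FRET as its standards and the pooled data as the
    known-stoichiometry sample.  A failing method is recorded as a failure
    row; the comparison continues.  If ``truth`` (an object with gamma_M
    and beta_X) is given, bias columns are added.
    """
    pooled = tuple(
        np.concatenate([_as_pixels(*populations[n])[i] for n in populations])
        for i in range(3)
    )
    # order populations by apparent FRET to pick Chen's extreme pair
    e_raw = {
        n: float(np.median(c / np.maximum(dd + c, 1e-300)))
        for n, (dd, c, aa) in
        ((n, _as_pixels(*p)) for n, p in populations.items())
    }
    ordered = sorted(populations, key=lambda n: e_raw[n])

    rows = []
    runners = {
        "quanti": lambda: quanti_calibration(*pooled, s0=s0),
        "lee": lambda: lee_calibration(*pooled),
        "chen": lambda: chen_calibration(
            populations[ordered[0]], populations[ordered[-1]], pooled, s0=s0
        ),
    }
    for name, run in runners.items():
        row: dict = {"method": name}
        try:
            res = run()
        except Exception as exc:  # a failing method must not stop the table
            row.update({"failed": True, "error": str(exc)})
            rows.append(row)
            continue
        row.update({
            "failed": False, "error": "",
            "gamma_like": res.gamma_like, "beta_like": res.beta_like,
        })
        for cname, med in _e_medians(populations, res.gamma_like).items():
            row[f"E_{cname}"] = med
        if truth is not None:
            row["gamma_bias"] = res.gamma_like - truth.gamma_M
            row["beta_bias"] = res.beta_like - truth.beta_X
        rows.append(row)
    return pd.DataFrame(rows)


def reduced_range_test(
    populations: dict[str, PixelSet],
    pairs: list[tuple[str, str]] | None = None,
    s0: float = 0.5,
) -> pd.DataFrame:
    """Refit all three methods on every two-construct subset.

    Emulates shrinking the FRET range of the calibration dataset; the
    spread of the recovered factors across pairs measures each method's
    sensitivity to that range.
    """
    if pairs is None:
        pairs = list(itertools.combinations(sorted(populations), 2))
    rows = []
    for pair in pairs:
        if len(set(pair)) != 2:
            raise ValueError(f"a pair must name two distinct constructs: {pair}")
        a, b = pair
        if a not in populations or b not in populations:
            raise KeyError(f"unknown construct in pair {pair}")
        sub = {a: populations[a], b: populations[b]}
        pooled = tuple(
            np.concatenate([_as_pixels(*sub[n])[i] for n in sub])
            for i in range(3)
        )
        for method, run in (
            ("quanti", lambda: quanti_calibration(*pooled, s0=s0)),
            ("lee", lambda: lee_calibration(*pooled)),
            ("chen", lambda: chen_calibration(sub[a], sub[b], pooled, s0=s0)),
        ):
            try:
                res = run()
                rows.append({"pair": f"{a}-{b}", "method": method,
                             "gamma_like": res.gamma_like,
                             "beta_like": res.beta_like, "failed": False})
            except Exception as exc:
                rows.append({"pair": f"{a}-{b}", "method": method,
                             "gamma_like": np.nan, "beta_like": np.nan,
                             "failed": True, "error": str(exc)})
    return pd.DataFrame(rows)


def relative_variation(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method (max - min)/mean of the factors across pairs."""
    rows = []
    for method, grp in table[~table["failed"]].groupby("method"):
        row = {"method": method}
        for col, key in (("gamma_like", "gamma"), ("beta_like", "beta")):
            vals = grp[col].to_numpy(dtype=float)
            row[f"rel_var_{key}"] = (
                float(np.ptp(vals) / np.mean(vals)) if vals.size else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def method_bootstrap_sd(
    dd, c, aa,
    s0: float = 0.5,
    sample_sizes=(1000, 10_000, 100_000),
    n_reps: int = 200,
    methods=("quanti", "lee"),
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Matched bootstrap dispersion of the factors for several methods.

    Every repetition draws one pixel subset and feeds the *same* subset to
    each method, so the dispersions are directly comparable.
    """
    rng = np.random.default_rng(rng)
    dd, c, aa = _as_pixels(dd, c, aa)
    n = dd.size
    fitters = {"quanti": lambda *p: quanti_calibration(*p, s0=s0),
               "lee": lambda *p: lee_calibration(*p)}
    rows = []
    for size in sample_sizes:
        if size > n:
            raise ValueError(f"sample size {size} exceeds dataset size {n}")
        acc = {m: {"gamma": [], "beta": [], "failed": 0} for m in methods}
        for _ in range(n_reps):
            idx = rng.choice(n, size=size, replace=False)
            sub = (dd[idx], c[idx], aa[idx])
            for m in methods:
                try:
                    res = fitters[m](*sub)
                except (CollinearityError, ValueError):
                    acc[m]["failed"] += 1
                    continue
                acc[m]["gamma"].append(res.gamma_like)
                acc[m]["beta"].append(res.beta_like)
        for m in methods:
            g, b = acc[m]["gamma"], acc[m]["beta"]
            rows.append({
                "sample_size": size, "method": m,
                "sd_gamma": float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
                "sd_beta": float(np.std(b, ddof=1)) if len(b) > 1 else 0.0,
                "n_ok": len(g), "n_failed": acc[m]["failed"],
            })
    return pd.DataFrame(rows)
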