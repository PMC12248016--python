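"""Flux-assay quantification and one-site ITC fitting.

Flux assays: Cl- efflux and H+ uptake are read from electrode traces.
The exchange cycle nets three elementary charges per cycle, so transport
is silent until valinomycin dissipates the membrane potential; rates are
taken as the post-valinomycin initial slope with the pre-valinomycin
leak slope subtracted. The H+ trace is recorded as extravesicular pH
and converted to mol/s through the buffer capacity. Per-transporter
(unitary) turnover divides the molar rate by the molar amount of
transporter (per homodimer, default 100 kDa); the Cl-/H+ stoichiometry
is the ratio of the two unitary rates, reported as mean +/- SEM across
replicates.

ITC: injection heats are fit with the single-site ("one set of sites")
Wiseman isotherm in the total-ligand formulation with per-injection
displaced-volume dilution, n fixed at 1. When the heat signal does not
rise above instrument noise the fit reports "n.h.d." (no heat detected)
with a Kd lower bound from the c = n[cell]/Kd >= 0.1 detectability rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger("clcpipe")

AVOGADRO = 6.02214076e23


# ---------------------------------------------------------------------------
# Flux traces -> rates
# ---------------------------------------------------------------------------

@dataclass
class SlopeFit:
    slope: float           # units of y per s, leak-corrected
    stderr: float
    baseline_slope: float


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and its standard error."""
    if len(t) < 2:
        raise ValueError("need at least two points for a slope")
    A = np.vstack([t, np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    n = len(t)
    if n > 2 and res.size:
        s2 = float(res[0]) / (n - 2)
        sxx = float(np.sum((t - t.mean()) ** 2))
        se = np.sqrt(s2 / sxx) if sxx > 0 else float("nan")
    else:
        se = 0.0
    return slope, se


def initial_rate_after_valinomycin(time_s: np.ndarray, y: np.ndarray,
                                   t_val: float, window_s: float = 30.0,
                                   baseline_window_s: float = 30.0,
                                   ) -> SlopeFit:
    """Linear slope over ``window_s`` after t_val, minus the slope over
    ``baseline_window_s`` before t_val (leak correction). Windows that
    extend past the trace are shortened with a warning."""
    time_s = np.asarray(time_s, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (time_s[0] <= t_val <= time_s[-1]):
        raise ValueError(f"t_val={t_val} outside trace span "
                         f"[{time_s[0]}, {time_s[-1]}]")
    if t_val + window_s > time_s[-1]:
        logger.warning("fit window extends past trace end; shortened to "
                       "%.3g s", time_s[-1] - t_val)
    post = (time_s >= t_val) & (time_s <= t_val + window_s)
    pre = (time_s >= t_val - baseline_window_s) & (time_s < t_val)
    slope_post, se = _linfit(time_s[post], y[post])
    if pre.sum() >= 2:
        slope_pre, _ = _linfit(time_s[pre], y[pre])
    else:
        slope_pre = 0.0
    slope = slope_post - slope_pre
    if not np.isfinite(slope):
        raise ValueError("non-finite slope fit")
    return SlopeFit(slope=slope, stderr=se, baseline_slope=slope_pre)


def chloride_rate_mol_s(trace_time_s: np.ndarray, chloride_mM: np.ndarray,
                        t_val: float, volume_L: float,
                        window_s: float = 30.0,
                        baseline_window_s: float = 30.0) -> float:
    """Cl- release rate in mol/s from an electrode trace in mM."""
    fit = initial_rate_after_valinomycin(trace_time_s, chloride_mM, t_val,
                                         window_s, baseline_window_s)
    return fit.slope * 1e-3 * volume_L     # mM/s -> mol/s


def ph_trace_to_proton_rate(trace_time_s: np.ndarray, ph: np.ndarray,
                            t_val: float, buffer_capacity: float,
                            volume_L: float, window_s: float = 30.0,
                            baseline_window_s: float = 30.0) -> float:
    """H+ uptake rate (mol/s, positive = into vesicles) from a pH trace.

    Uptake removes H+ from the measured extravesicular solution, so the
    recorded pH rises; rate = capacity * volume * d(pH)/dt.
    """
    fit = initial_rate_after_valinomycin(trace_time_s, ph, t_val, window_s,
                                         baseline_window_s)
    return buffer_capacity * volume_L * fit.slope


# ---------------------------------------------------------------------------
# Unitary turnover and stoichiometry
# ---------------------------------------------------------------------------

@dataclass
class TurnoverResult:
    """Unitary rates (ions/s per transporter) and Cl-/H+ stoichiometry,
    mean +/- SEM across replicates."""

    r_cl: float
    r_h: float
    stoichiometry: float
    r_cl_sem: float = float("nan")
    r_h_sem: float = float("nan")
    stoichiometry_sem: float = float("nan")
    per_replicate: list = field(default_factory=list)
    n: int = 1


def transporter_amount_mol(protein_ug: float,
                           transporter_kda: float = 100.0) -> float:
    """Moles of transporter from protein mass; "per transporter" means
    per homodimer (default molar mass 100 kDa)."""
    return protein_ug * 1e-6 / (transporter_kda * 1e3)


def unitary_turnover(cl_rates_mol_s: Sequence[float],
                     h_rates_mol_s: Sequence[float],
                     protein_ug: float,
                     transporter_kda: float = 100.0) -> TurnoverResult:
    """Per-transporter turnover and stoichiometry from replicate molar
    rates. Stoichiometry is formed per replicate then averaged; it is
    invariant to common amplitude rescaling and to protein-mass errors
    (the transporter count cancels in the ratio)."""
    n_t = transporter_amount_mol(protein_ug, transporter_kda)
    cl = np.asarray(cl_rates_mol_s, dtype=float) / n_t   # ions/s (mol/mol)
    h = np.asarray(h_rates_mol_s, dtype=float) / n_t
    if len(cl) != len(h):
        raise ValueError("replicate lists must align")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(h != 0, cl / h, np.inf)
    n = len(cl)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return TurnoverResult(
        r_cl=float(np.mean(cl)), r_h=float(np.mean(h)),
        stoichiometry=float(np.mean(s)),
        r_cl_sem=sem(cl), r_h_sem=sem(h), stoichiometry_sem=sem(s),
        per_replicate=list(zip(cl.tolist(), h.tolist(), s.tolist())),
        n=n,
    )


def stoichiometry_from_rates(r_cl: float, r_h: float) -> float:
    """Cl-/H+ coupling ratio from unitary rates (e.g. 2300/1100)."""
    if r_h == 0:
        raise ZeroDivisionError("H+ rate is zero; stoichiometry undefined")
    return r_cl / r_h


def net_charge_per_exchange(n_cl_out: int = 2, n_h_in: int = 1) -> int:
    """Elementary charges moved across the membrane per exchange cycle:
    each Cl- out and each H+ in both move +1 inward, so the canonical
    2 Cl- out / 1 H+ in cycle nets 3 charges."""
    return abs(n_cl_out + n_h_in)


# ---------------------------------------------------------------------------
# ITC: Wiseman one-site isotherm
# ---------------------------------------------------------------------------

def wiseman_heats(kd_M: float, dh_cal_mol: float, n_sites: float,
                  cell_M: float, syringe_M: float, cell_volume_L: float,
                  inj_volumes_L: np.ndarray) -> np.ndarray:
    """Per-injection heats (µcal) of the single-site binding isotherm,
    total-ligand formulation with displaced-volume dilution.

    Cumulative concentrations after injection i (V0 = cell volume,
    dV = cumulative injected volume):
        Mt = M0 (1 - dV/2V0) / (1 + dV/2V0)
        Xt = X0 (dV/V0) / (1 + dV/2V0)
    Cumulative heat Q_i and differential heat with the displaced-volume
    correction dQ_i = Q_i - Q_{i-1} + (dV_i/V0)(Q_i + Q_{i-1})/2.
    """
    inj = np.asarray(inj_volumes_L, dtype=float)
    v0 = cell_volume_L
    dv = np.cumsum(inj)
    mt = cell_M * (1 - dv / (2 * v0)) / (1 + dv / (2 * v0))
    xt = syringe_M * (dv / v0) / (1 + dv / (2 * v0))
    nm = n_sites * mt
    with np.errstate(invalid="ignore"):
        b = 1 + xt / nm + kd_M / nm
        theta_term = b - np.sqrt(b ** 2 - 4 * xt / nm)
    q = nm * dh_cal_mol * v0 / 2 * theta_term      # cumulative heat, cal
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev + (inj / v0) * (q + q_prev) / 2
    return dq * 1e6                                 # µcal


@dataclass
class ITCFit:
    kd_mM: float
    dh_kcal: float
    n_sites: float
    baseline_ucal: float
    status: str                     # "ok" | "n.h.d."
    c_value: float
    kd_lower_bound_mM: Optional[float] = None
    residual_rms_ucal: float = float("nan")


def fit_itc_one_site(inj_volumes_uL: np.ndarray, heats_ucal: np.ndarray,
                     cell_uM: float, syringe_mM: float,
                     cell_volume_mL: float = 1.4, fix_n: float = 1.0,
                     noise_ucal: Optional[float] = None,
                     nhd_k: float = 5.0,
                     reference_heats_ucal: Optional[np.ndarray] = None,
                     ) -> ITCFit:
    """Least-squares one-site fit of injection heats (n fixed).

    Reference (buffer-into-protein) heats are subtracted when provided.
    If the heat signal beyond the best linear dilution trend is below
    ``nhd_k`` times the noise, the titration is reported as n.h.d. with
    the Kd lower bound implied by the c >= 0.1 detectability rule.
    """
    inj = np.asarray(inj_volumes_uL, dtype=float) * 1e-6
    heats = np.asarray(heats_ucal, dtype=float)
    if reference_heats_ucal is not None:
        heats = heats - np.asarray(reference_heats_ucal, dtype=float)
    if len(heats) < 5:
        raise ValueError(f"underdetermined ITC fit: {len(heats)} injections")
    cell_M = cell_uM * 1e-6
    syr_M = syringe_mM * 1e-3
    v0 = cell_volume_mL * 1e-3

    # noise estimate: provided, or scatter about the local linear trend of
    # the last third of the titration (near-saturation / dilution tail)
    if noise_ucal is None:
        tail = heats[-max(5, len(heats) // 3):]
        x = np.arange(len(tail), dtype=float)
        resid = tail - np.polyval(np.polyfit(x, tail, 1), x)
        noise_ucal = float(np.std(resid, ddof=2)) if len(tail) > 3 else 0.0
        noise_ucal = max(noise_ucal, 1e-3)

    # n.h.d. test: curvature of the heat sequence above the best linear
    # (dilution-like) trend, compared with instrument noise
    idx = np.arange(len(heats), dtype=float)
    lin = np.polyval(np.polyfit(idx, heats, 1), idx)
    signal = float(np.max(np.abs(heats - lin)))
    if signal < nhd_k * noise_ucal:
        bound_mM = fix_n * cell_uM * 1e-3 / 0.1      # c = 0.1 rule, in mM
        logger.info("ITC: no heat detected (signal %.3g µcal < %g x %.3g); "
                    "Kd lower bound %.3g mM", signal, nhd_k, noise_ucal,
                    bound_mM)
        return ITCFit(kd_mM=float("nan"), dh_kcal=float("nan"),
                      n_sites=fix_n, baseline_ucal=float(np.mean(heats)),
                      status="n.h.d.", c_value=0.0,
                      kd_lower_bound_mM=bound_mM)

    def resid(p):
        log_kd, dh_kcal, base = p
        model = wiseman_heats(10.0 ** log_kd, dh_kcal * 1e3, fix_n, cell_M,
                              syr_M, v0, inj) + base
        return model - heats

    dh0 = heats[0] / max(cell_M * v0 * 1e6 * 1e3, 1e-12) / 2  # rough kcal/mol
    best = None
    for log_kd0 in (-4.5, -3.5, -3.0, -2.5, -2.0):
        sol = least_squares(resid, x0=[log_kd0, dh0 if dh0 else -1.0, 0.0],
                            bounds=([-8, -100, -1e3], [0, 100, 1e3]))
        if best is None or sol.cost < best.cost:
            best = sol
    kd_M = 10.0 ** best.x[0]
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    c = fix_n * cell_M / kd_M
    return ITCFit(kd_mM=kd_M * 1e3, dh_kcal=float(best.x[1]),
                  n_sites=fix_n, baseline_ucal=float(best.x[2]),
                  status="ok", c_value=float(c), residual_rms_ucal=rms)
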