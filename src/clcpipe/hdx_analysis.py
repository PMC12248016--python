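"""Differential HDX-MS analysis with pH normalization.

Amide hydrogen exchange is base-catalyzed over the pH range used here
(3.0-6.5), so the intrinsic rate scales as 10**dpH: a labeling time t at
pH p is equivalent to t * 10**(p - ref) at the reference pH. Conditions
measured at different pH are therefore compared at *matched* normalized
times (e.g. 20 s at pH 6.5 against 2000 s at pH 4.5, a 100-fold factor
for the 2-unit shift). Raw uptake is corrected for back-exchange with a
fully deuterated (FD) control: D_corr = D_raw * N_ex / D_FD, where N_ex
is the number of exchangeable amides (peptide length minus the first two
residues and prolines beyond position 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger("clcpipe")


# ---------------------------------------------------------------------------
# pH normalization
# ---------------------------------------------------------------------------

def intrinsic_rate_factor(ph_a: float, ph_b: float) -> float:
    """Fold change of the intrinsic exchange rate between two pH values
    (base-catalyzed regime): 10**(ph_a - ph_b)."""
    return 10.0 ** (ph_a - ph_b)


def normalize_time(t_s: float | np.ndarray, ph: float,
                   ref_ph: float) -> float | np.ndarray:
    """Equivalent labeling time at ``ref_ph``: t * 10**(ph - ref_ph)."""
    return np.asarray(t_s, dtype=float) * intrinsic_rate_factor(ph, ref_ph) \
        if isinstance(t_s, (list, tuple, np.ndarray)) \
        else t_s * intrinsic_rate_factor(ph, ref_ph)


def match_timepoints(times_a: Sequence[float], ph_a: float,
                     times_b: Sequence[float], ph_b: float,
                     ref_ph: float = 3.0, rel_tol: float = 0.05,
                     ) -> list[tuple[float, float]]:
    """Pair raw times whose normalized times agree within ``rel_tol``.

    Each time is used at most once; pairs are ordered by normalized
    time. Returns [] (with a warning) when nothing matches.
    """
    na = [(t, normalize_time(t, ph_a, ref_ph)) for t in sorted(set(times_a))]
    nb = [(t, normalize_time(t, ph_b, ref_ph)) for t in sorted(set(times_b))]
    pairs = []
    used_b: set[float] = set()
    for ta, za in na:
        best = None
        for tb, zb in nb:
            if tb in used_b or zb == 0:
                continue
            rel = abs(za - zb) / zb
            if rel <= rel_tol and (best is None or rel < best[0]):
                best = (rel, tb, zb)
        if best is not None:
            used_b.add(best[1])
            pairs.append((ta, best[1], za))
    if not pairs:
        logger.warning("no matched time points between pH %.2f and %.2f",
                       ph_a, ph_b)
        return []
    pairs.sort(key=lambda p: p[2])
    return [(ta, tb) for ta, tb, _ in pairs]


# ---------------------------------------------------------------------------
# Dataset container and back-exchange correction
# ---------------------------------------------------------------------------

def exchangeable_amides(sequence: str) -> int:
    """Exchangeable backbone amides of a peptide: length minus the first
    two residues (N-terminus and fast-back-exchanging first position
    after cleavage) minus prolines beyond position 2."""
    n = len(sequence) - 2 - sequence[2:].count("P")
    return max(n, 0)


@dataclass
class UptakeDataset:
    """Peptide-resolved uptake observations plus FD control.

    peptides:     peptide_map schema (peptide_id, start, end, sequence).
    observations: hdx_uptake schema rows.
    fd_control:   per-peptide fully deuterated uptake (Da).
    """

    peptides: pd.DataFrame
    observations: pd.DataFrame
    fd_control: Optional[pd.DataFrame] = None
    ref_ph: float = 3.0
    corrected: bool = False

    def __post_init__(self) -> None:
        if (self.observations["uptake_Da"] < 0).any():
            raise ValueError("uptake must be >= 0")
        bad = self.peptides[self.peptides.start > self.peptides.end]
        if len(bad):
            raise ValueError(f"peptides with start > end: "
                             f"{bad.peptide_id.tolist()}")

    def times_at(self, ph: float) -> np.ndarray:
        obs = self.observations
        return np.sort(obs.loc[obs.pH == ph, "time_s"].unique())

    def ph_values(self) -> np.ndarray:
        return np.sort(self.observations.pH.unique())


def back_exchange_correct(dataset: UptakeDataset) -> UptakeDataset:
    """Correct uptake for deuterium loss during analysis using the FD
    control: D_corr = D_raw * N_ex / D_FD per peptide. Peptides whose FD
    uptake is <= 0 are excluded (logged). The corrected FD control
    equals N_ex exactly."""
    if dataset.fd_control is None:
        raise ValueError("back-exchange correction requires an FD control")
    fd = dataset.fd_control.set_index("peptide_id")["uptake_Da"]
    n_ex = {p.peptide_id: exchangeable_amides(p.sequence)
            for p in dataset.peptides.itertuples()}
    keep, factor = [], {}
    for pid, d_fd in fd.items():
        if d_fd <= 0:
            logger.warning("peptide %s excluded: FD control uptake %.3g <= 0",
                           pid, d_fd)
            continue
        keep.append(pid)
        factor[pid] = n_ex.get(pid, 0) / d_fd
    obs = dataset.observations[
        dataset.observations.peptide_id.isin(keep)].copy()
    obs["uptake_Da"] = obs["uptake_Da"] * obs["peptide_id"].map(factor)
    peptides = dataset.peptides[dataset.peptides.peptide_id.isin(keep)]
    fd_corr = pd.DataFrame({
        "peptide_id": keep,
        "uptake_Da": [float(n_ex.get(p, 0)) for p in keep],
    })
    return UptakeDataset(peptides=peptides.reset_index(drop=True),
                         observations=obs.reset_index(drop=True),
                         fd_control=fd_corr, ref_ph=dataset.ref_ph,
                         corrected=True)


# ---------------------------------------------------------------------------
# Differential maps
# ---------------------------------------------------------------------------

@dataclass
class DifferentialMap:
    """Matrix of uptake differences D(A) - D(B) at matched normalized
    exchange times; antisymmetric under swapping A and B."""

    peptide_ids: list
    matched_times: list          # [(t_A, t_B), ...] ordered by normalized t
    delta: np.ndarray            # (n_peptides, n_matched)
    sd: np.ndarray               # propagated SD where replicates exist
    ph_a: float
    ph_b: float
    final_time_index: int = -1

    @property
    def final_time_vector(self) -> np.ndarray:
        """Per-peptide difference at the final matched time point (the
        column painted onto the structure)."""
        return self.delta[:, self.final_time_index]


def differential_map(dataset: UptakeDataset, ph_a: float, ph_b: float,
                     ref_ph: Optional[float] = None,
                     rel_tol: float = 0.05) -> DifferentialMap:
    """Replicate-mean uptake differences per peptide at matched times.

    Per-cell SD is propagated (sqrt of summed variances) where
    replicates exist in both conditions.
    """
    if ref_ph is None:
        ref_ph = dataset.ref_ph
    pairs = match_timepoints(dataset.times_at(ph_a), ph_a,
                             dataset.times_at(ph_b), ph_b,
                             ref_ph=ref_ph, rel_tol=rel_tol)
    pids = dataset.peptides.peptide_id.tolist()
    obs = dataset.observations
    delta = np.full((len(pids), len(pairs)), np.nan)
    sd = np.full((len(pids), len(pairs)), np.nan)
    g = obs.groupby(["peptide_id", "pH", "time_s"])["uptake_Da"]
    means = g.mean()
    var = g.var(ddof=1)
    for j, (ta, tb) in enumerate(pairs):
        for i, pid in enumerate(pids):
            try:
                ma = means.loc[(pid, ph_a, ta)]
                mb = means.loc[(pid, ph_b, tb)]
            except KeyError:
                continue
            delta[i, j] = ma - mb
            va = var.get((pid, ph_a, ta), np.nan)
            vb = var.get((pid, ph_b, tb), np.nan)
            if np.isfinite(va) and np.isfinite(vb):
                sd[i, j] = np.sqrt(va + vb)
    return DifferentialMap(peptide_ids=pids, matched_times=pairs,
                           delta=delta, sd=sd, ph_a=ph_a, ph_b=ph_b)


def spread_to_residues(peptides: pd.DataFrame, values: np.ndarray,
                       sequence_length: int) -> np.ndarray:
    """Spread per-peptide values onto residues by averaging overlapping
    peptides (for structure painting); uncovered residues are NaN."""
    acc = np.zeros(sequence_length)
    cnt = np.zeros(sequence_length)
    for v, pep in zip(values, peptides.itertuples()):
        if not np.isfinite(v):
            continue
        acc[pep.start - 1:pep.end] += v
        cnt[pep.start - 1:pep.end] += 1
    out = np.full(sequence_length, np.nan)
    cov = cnt > 0
    out[cov] = acc[cov] / cnt[cov]
    return out


# ---------------------------------------------------------------------------
# Uptake-kinetics fitting
# ---------------------------------------------------------------------------

@dataclass
class UptakeFit:
    amplitudes: np.ndarray
    rates: np.ndarray            # s^-1
    residual_rms: float
    converged: bool


def fit_uptake_kinetics(times_s: np.ndarray, uptake: np.ndarray,
                        n_components: int = 1,
                        n_ex: Optional[float] = None) -> UptakeFit:
    """Nonlinear least squares of D(t) = sum_i A_i (1 - exp(-k_i t))
    with A_i >= 0 and sum A_i <= N_ex (when given)."""
    times_s = np.asarray(times_s, dtype=float)
    uptake = np.asarray(uptake, dtype=float)
    n_par = 2 * n_components
    if len(times_s) < max(2, n_par):
        raise ValueError(
            f"underdetermined: {len(times_s)} time point(s) for "
            f"{n_par} parameters")
    if np.allclose(uptake, 0.0):
        return UptakeFit(amplitudes=np.zeros(n_components),
                         rates=np.zeros(n_components),
                         residual_rms=0.0, converged=True)

    def model(t, *p):
        a = np.asarray(p[:n_components])
        k = np.asarray(p[n_components:])
        return np.sum(a[:, None] * (1 - np.exp(-np.outer(k, t))), axis=0)

    amp_max = float(n_ex) if n_ex is not None else max(uptake.max() * 2, 1.0)
    a0 = np.full(n_components, uptake.max() / n_components)
    t_mid = np.median(times_s[times_s > 0]) or 1.0
    k0 = np.array([1.0 / t_mid * 10.0 ** (i - n_components // 2)
                   for i in range(n_components)])
    lb = np.concatenate([np.zeros(n_components), np.full(n_components, 1e-12)])
    ub = np.concatenate([np.full(n_components, amp_max),
                         np.full(n_components, 1e6)])
    try:
        popt, _ = curve_fit(model, times_s, uptake,
                            p0=np.concatenate([a0, k0]), bounds=(lb, ub),
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt = np.concatenate([a0, k0])
        converged = False
    resid = uptake - model(times_s, *popt)
    order = np.argsort(popt[n_components:])[::-1]
    return UptakeFit(amplitudes=popt[:n_components][order],
                     rates=popt[n_components:][order],
                     residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                     converged=converged)


# ---------------------------------------------------------------------------
# Coverage statistics
# ---------------------------------------------------------------------------

@dataclass
class CoverageStats:
    coverage_fraction: float      # covered residues / sequence length
    peptide_count: int
    mean_peptide_length: float
    mean_redundancy: float        # sum of lengths / covered residues
    undefined_redundancy: bool = False


def coverage_stats(peptide_map: pd.DataFrame,
                   sequence_length: int) -> CoverageStats:
    """Sequence coverage, peptide count, mean length and mean redundancy
    (per-covered-residue peptide depth) from a peptide map."""
    covered = np.zeros(sequence_length, dtype=int)
    lengths = []
    for pep in peptide_map.itertuples():
        covered[pep.start - 1:pep.end] += 1
        lengths.append(pep.end - pep.start + 1)
    n_cov = int((covered > 0).sum())
    if not lengths:
        logger.warning("empty peptide map: coverage 0, redundancy undefined")
        return CoverageStats(0.0, 0, float("nan"), float("nan"),
                             undefined_redundancy=True)
    return CoverageStats(
        coverage_fraction=n_cov / sequence_length,
        peptide_count=len(lengths),
        mean_peptide_length=float(np.mean(lengths)),
        mean_redundancy=float(np.sum(lengths) / n_cov) if n_cov else float("nan"),
        undefined_redundancy=n_cov == 0,
    )
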