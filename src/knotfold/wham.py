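"""WHAM density-of-states estimation and thermodynamic observables.

Multi-temperature histograms over (E, Q, knot state) are combined into a
maximum-likelihood density of states g by iterating the self-consistency
equations

    g(m) = sum_k H_k(m) / sum_k n_k exp(f_k - E_m / T_k)
    exp(-f_k) = sum_m g(m) exp(-E_m / T_k)

to a fixed point (all arithmetic in log space).  Canonical averages follow
by reweighting: internal energy U(T), heat capacity
CV = (<E^2> - <E>^2)/T^2, melting temperature Tm (CV peak), the peak's
FWHM/Tm cooperativity ratio, and knotting probability profiles pk(T) and
pk(Q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp


class WhamError(RuntimeError):
    pass


@dataclass
class DensityOfStates:
    """Estimated log density of states over (E, Q, knot-state) bins."""

    log_g: np.ndarray          # (nE, nQ, 2), -inf in unoccupied bins
    e_edges: np.ndarray
    q_edges: np.ndarray
    f: np.ndarray              # per-temperature log normalisers
    temperatures: np.ndarray
    n_iter: int

    @property
    def e_centers(self) -> np.ndarray:
        return 0.5 * (self.e_edges[:-1] + self.e_edges[1:])

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])

    # -- canonical averages ------------------------------------------------
    def _logw(self, t: float) -> np.ndarray:
        return self.log_g - self.e_centers[:, None, None] / t

    def internal_energy(self, t: float) -> float:
        lw = self._logw(t)
        ln_z = logsumexp(lw)
        return float(np.sum(self.e_centers[:, None, None]
                            * np.exp(lw - ln_z)))

    def heat_capacity(self, t: float) -> float:
        lw = self._logw(t)
        ln_z = logsumexp(lw)
        p = np.exp(lw - ln_z)
        e = self.e_centers[:, None, None]
        mean = np.sum(e * p)
        mean2 = np.sum(e * e * p)
        return float((mean2 - mean * mean) / t ** 2)

    def knotting_probability(self, t: float) -> float:
        lw = self._logw(t)
        ln_z = logsumexp(lw)
        return float(np.sum(np.exp(lw[:, :, 1] - ln_z)))


def _auto_e_edges(energies: np.ndarray) -> np.ndarray:
    lo, hi = float(energies.min()), float(energies.max())
    if hi - lo < 1e-12:
        return np.array([lo - 0.025, lo + 0.025])
    width = max(0.05, (hi - lo) / 400.0)
    n = int(np.ceil((hi - lo) / width))
    return np.linspace(lo - 1e-9, hi + 1e-9, n + 1)


def wham_fit(energies: Sequence[np.ndarray], temperatures,
             q: Optional[Sequence[np.ndarray]] = None,
             knotted: Optional[Sequence[np.ndarray]] = None,
             e_edges: Optional[np.ndarray] = None,
             q_edges: Optional[np.ndarray] = None,
             tol: float = 1e-8, max_iter: int = 100000,
             min_overlap: float = 0.01) -> DensityOfStates:
    """Fit the density of states from per-temperature samples.

    ``energies[k]`` are the energy samples collected at ``temperatures[k]``;
    ``q`` and ``knotted`` are optional parallel sample lists.  Energy bins
    default to width max(0.05, range/400) reduced units; Q bins should be
    one per contact count (pass ``q_edges``) and default to 51 uniform bins.
    Convergence: max |Delta f_k| < tol between sweeps.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    n_temp = temperatures.size
    if len(energies) != n_temp:
        raise WhamError("need one energy sample array per temperature")
    energies = [np.asarray(e, dtype=float) for e in energies]
    if q is None:
        q = [np.zeros_like(e) for e in energies]
    if knotted is None:
        knotted = [np.zeros(e.shape, dtype=bool) for e in energies]
    all_e = np.concatenate(energies)
    if e_edges is None:
        e_edges = _auto_e_edges(all_e)
    if q_edges is None:
        q_edges = np.linspace(0.0, 1.0 + 1e-9, 52)

    # adjacent-ladder overlap diagnostics
    hists = [np.histogram(e, bins=e_edges)[0] for e in energies]
    for k in range(n_temp - 1):
        a, b = hists[k], hists[k + 1]
        both = (a > 0) & (b > 0)
        ov = min(a[both].sum() / max(1, a.sum()),
                 b[both].sum() / max(1, b.sum()))
        if not both.any():
            raise WhamError(
                f"energy histograms at T={temperatures[k]:g} and "
                f"T={temperatures[k + 1]:g} do not overlap; ladder too sparse")
        if ov < min_overlap:
            warnings.warn(
                f"adjacent-temperature overlap below {min_overlap:.0%} "
                f"between T={temperatures[k]:g} and T={temperatures[k + 1]:g}",
                stacklevel=2)

    nE, nQ = e_edges.size - 1, q_edges.size - 1
    h = np.zeros((n_temp, nE, nQ, 2))
    for k in range(n_temp):
        kn = np.asarray(knotted[k]).astype(int)
        for state in (0, 1):
            sel = kn == state
            if sel.any():
                h[k, :, :, state], _, _ = np.histogram2d(
                    energies[k][sel], np.asarray(q[k])[sel],
                    bins=(e_edges, q_edges))
    n_k = h.reshape(n_temp, -1).sum(axis=1)
    h_tot = h.sum(axis=0)
    occupied = h_tot > 0
    e_centers = 0.5 * (e_edges[:-1] + e_edges[1:])
    beta_e = e_centers[None, :] / temperatures[:, None]     # (K, nE)

    with np.errstate(divide="ignore"):
        log_h_tot = np.log(h_tot)
        log_n_k = np.log(n_k)

    f = np.zeros(n_temp)
    log_g_e = None
    for it in range(1, int(max_iter) + 1):
        # denominator depends on E only: (K,nE) -> (nE,)
        log_den = logsumexp(log_n_k[:, None] + f[:, None] - beta_e, axis=0)
        log_g = np.where(occupied,
                         log_h_tot - log_den[:, None, None], -np.inf)
        log_g_e = logsumexp(log_g, axis=(1, 2))             # (nE,)
        f_new = -logsumexp(log_g_e[None, :] - beta_e, axis=1)
        f_new = f_new - f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise WhamError(f"WHAM did not converge in {max_iter} iterations "
                        f"(last |df| = {delta:.2e})")
    log_den = logsumexp(log_n_k[:, None] + f[:, None] - beta_e, axis=0)
    log_g = np.where(occupied, log_h_tot - log_den[:, None, None], -np.inf)
    return DensityOfStates(log_g, np.asarray(e_edges), np.asarray(q_edges),
                           f, temperatures, it)


def wham_from_samples(samples: pd.DataFrame, temperatures,
                      n_contacts: Optional[int] = None,
                      **kw) -> DensityOfStates:
    """Fit WHAM from a run_simulation sample table.

    With ``n_contacts`` the Q axis gets one bin per formed-contact count.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    groups = dict(list(samples.groupby("T_index")))
    energies, qs, kns = [], [], []
    for k in range(temperatures.size):
        if k not in groups:
            raise WhamError(f"no samples for temperature index {k}")
        g = groups[k]
        energies.append(g["E"].to_numpy())
        qs.append(g["Q"].to_numpy())
        kns.append(g["knotted"].to_numpy().astype(bool)
                   if "knotted" in g.columns else np.zeros(len(g), bool))
    if n_contacts and "q_edges" not in kw:
        kw["q_edges"] = (np.arange(n_contacts + 2) - 0.5) / n_contacts
    return wham_fit(energies, temperatures, q=qs, knotted=kns, **kw)


def thermo_curves(dos: DensityOfStates, t_grid) -> tuple:
    """U(T) and CV(T) on a temperature grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    u = np.array([dos.internal_energy(t) for t in t_grid])
    cv = np.array([dos.heat_capacity(t) for t in t_grid])
    return u, cv


def melting_and_width(t_grid, cv) -> tuple:
    """(Tm, FWHM, FWHM/Tm) from a heat-capacity curve.

    Tm is the grid argmax; the full width at half maximum interpolates the
    two half-maximum crossings linearly.  The peak must lie strictly inside
    the grid and both crossings must exist.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    cv = np.asarray(cv, dtype=float)
    i = int(np.argmax(cv))
    if i == 0 or i == cv.size - 1:
        raise WhamError("CV peak at the grid boundary; widen the grid")
    tm = float(t_grid[i])
    half = cv[i] / 2.0
    left = np.where(cv[:i] <= half)[0]
    right = np.where(cv[i:] <= half)[0]
    if left.size == 0 or right.size == 0:
        raise WhamError("CV does not fall to half maximum inside the grid")
    l0 = left[-1]
    t_left = np.interp(half, [cv[l0], cv[l0 + 1]], [t_grid[l0], t_grid[l0 + 1]])
    r0 = i + right[0]
    t_right = np.interp(half, [cv[r0], cv[r0 - 1]], [t_grid[r0], t_grid[r0 - 1]])
    fwhm = float(t_right - t_left)
    return tm, fwhm, fwhm / tm


def knotting_profiles(dos: DensityOfStates, t_grid,
                      t_ref: Optional[float] = None) -> tuple:
    """pk(T) on the grid and pk(Q) at the reference temperature.

    pk(T) is the canonical average of the knot indicator; pk(Q) is the
    knotted fraction per Q bin of the reweighted density at ``t_ref``
    (default: Tm from the CV curve on the grid).  Empty Q bins are NaN.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    pk_t = np.array([dos.knotting_probability(t) for t in t_grid])
    if t_ref is None:
        _, cv = thermo_curves(dos, t_grid)
        t_ref = float(t_grid[int(np.argmax(cv))])
    lw = dos.log_g - dos.e_centers[:, None, None] / t_ref
    with np.errstate(invalid="ignore"):
        w = np.exp(lw - logsumexp(lw))
    tot = w.sum(axis=(0, 2))
    knot = w[:, :, 1].sum(axis=0)
    pk_q = np.where(tot > 0, knot / np.where(tot > 0, tot, 1.0), np.nan)
    return pk_t, (dos.q_centers, pk_q, t_ref)


# ---------------------------------------------------------------------------
# equilibration cross-check

@dataclass
class EquilibrationReport:
    passed: bool
    max_sigma: float          # worst |difference| / combined SE
    worst: tuple              # (stat, run_a, run_b, T)
    table: pd.DataFrame


def _block_bootstrap_se(x: np.ndarray, stat, n_blocks: int = 50,
                        n_boot: int = 200, seed: int = 0) -> float:
    """SE of ``stat`` over time-ordered samples via block bootstrap."""
    n = x.size
    n_blocks = min(n_blocks, n)
    blocks = np.array_split(np.arange(n), n_blocks)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        idx = np.concatenate([blocks[i] for i in pick])
        vals[b] = stat(x[idx])
    return float(vals.std(ddof=1))


def check_equilibration(runs: Sequence[pd.DataFrame], temperatures,
                        n_blocks: int = 50, n_boot: int = 200,
                        seed: int = 2024, n_sigma: float = 3.0
                        ) -> EquilibrationReport:
    """Cross-check independent runs for mutual equilibrium consistency.

    For every ladder temperature, per-run direct averages U = <E> and
    CV = var(E)/T^2 are compared pairwise across runs; the check passes iff
    every difference is within ``n_sigma`` combined block-bootstrap standard
    errors.  Runs started from different states (native/denatured) or with
    different move sets can only agree if all of them reached equilibrium,
    so this is the standard four-run equilibration test.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    stats = []   # per run: {T_index: (U, seU, CV, seCV)}
    for run_id, df in enumerate(runs):
        per_t = {}
        for k, grp in df.groupby("T_index"):
            k = int(k)
            if k >= temperatures.size:
                raise WhamError("run has temperature indices outside the "
                                "ladder (mismatched ladders?)")
            e = grp.sort_values("mcs")["E"].to_numpy()
            t = temperatures[k]
            per_t[k] = (
                e.mean(),
                _block_bootstrap_se(e, np.mean, n_blocks, n_boot,
                                    seed + 97 * run_id + k),
                e.var() / t ** 2,
                _block_bootstrap_se(e, lambda v: v.var() / t ** 2, n_blocks,
                                    n_boot, seed + 97 * run_id + k + 31),
            )
        if set(per_t) != set(range(temperatures.size)):
            raise WhamError("run does not cover the full ladder "
                            "(mismatched ladders?)")
        stats.append(per_t)

    rows = []
    max_sigma, worst = 0.0, None
    for a in range(len(runs)):
        for b in range(a + 1, len(runs)):
            for k in range(temperatures.size):
                ua, sua, cva, scva = stats[a][k]
                ub, sub, cvb, scvb = stats[b][k]
                for name, va, sa, vb, sb in (
                        ("U", ua, sua, ub, sub),
                        ("CV", cva, scva, cvb, scvb)):
                    se = np.hypot(sa, sb)
                    sig = abs(va - vb) / se if se > 0 else (
                        0.0 if va == vb else np.inf)
                    rows.append({"stat": name, "run_a": a, "run_b": b,
                                 "T": temperatures[k], "diff": va - vb,
                                 "combined_se": se, "sigma": sig})
                    if sig > max_sigma:
                        max_sigma, worst = sig, (name, a, b,
                                                 float(temperatures[k]))
    table = pd.DataFrame(rows)
    return EquilibrationReport(passed=bool(max_sigma <= n_sigma),
                               max_sigma=float(max_sigma), worst=worst,
                               table=table)


def plot_thermo(t_grid, u, cv, ax=None):
    """Quick-look plot of U(T) and CV(T); returns the matplotlib axes."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(8, 3))
    ax[0].plot(t_grid, u)
    ax[0].set_xlabel("T (reduced)")
    ax[0].set_ylabel("U (reduced)")
    ax[1].plot(t_grid, cv)
    ax[1].set_xlabel("T (reduced)")
    ax[1].set_ylabel("$C_V$ (reduced)")
    return ax
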