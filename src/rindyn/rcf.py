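"""NH bond-vector rotational correlation: P2 autocorrelation, model-free fit.

The reorientational dynamics of a protein backbone are summarised by the
second-rank rotational correlation function C(tau) = <P2(u(t).u(t+tau))>
of the amide N-H unit vector, with P2(x) = (3x^2 - 1)/2.  C decays as
exp(-6 D tau) for isotropic rotational diffusion with diffusion constant D.
A two-parameter model-free curve y = a0 + (1 - a0) exp(-x/a1) is fitted to
the averaged RCF; the rotational correlation time tau_c is the analytic
integral of the fitted curve over the fit window and D_iso = 1/(6 tau_c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, FitError
from .structure import Topology, Trajectory
from .synth import amide_hydrogen

__all__ = [
    "RCFSeries",
    "ModelFreeFit",
    "RotationalStats",
    "nh_vectors",
    "p2_acf",
    "fit_model_free",
    "rotational_stats",
]


@dataclass
class RCFSeries:
    """P2 autocorrelation values over lag times (ps); C(0) = 1."""

    lags: np.ndarray
    values: np.ndarray
    n_vectors: int = 1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# lag_ps\trcf\n")
            for t, v in zip(self.lags, self.values):
                fh.write(f"{t:.6g}\t{v:.8g}\n")


@dataclass
class ModelFreeFit:
    """Parameters of y = a0 + (1 - a0) exp(-x / a1)."""

    a0: float
    a1: float
    residual_norm: float
    degenerate: bool = False


@dataclass
class RotationalStats:
    tau_c: float  # ps
    d_iso: float  # ps^-1


def nh_vectors(traj: Trajectory, topology: Topology | None = None) -> np.ndarray:
    """Unit N->H vectors per frame per eligible residue.

    Prolines and chain N-termini are excluded (no amide hydrogen); missing
    hydrogens are constructed geometrically.  Returns an array of shape
    (n_frames, n_eligible, 3).
    """
    top = topology or traj.topology
    sites = []
    prev_c: dict[int, int] = {}
    for ridx, res in enumerate(top.residues):
        if not res.is_protein or res.name == "PRO":
            continue
        names = {top.atoms[i].name: i for i in res.atom_indices}
        if "N" not in names:
            continue
        h_index = names.get("H", names.get("HN"))
        if h_index is None:
            if ridx == 0:
                continue
            prev = top.residues[ridx - 1]
            if prev.chain_id != res.chain_id or "CA" not in names:
                continue
            prev_names = {top.atoms[i].name: i for i in prev.atom_indices}
            if "C" not in prev_names:
                continue
            sites.append((names["N"], -1, names["CA"], prev_names["C"]))
        else:
            # chain N-terminus check: previous residue in same chain?
            if ridx == 0 or top.residues[ridx - 1].chain_id != res.chain_id:
                continue
            sites.append((names["N"], h_index, -1, -1))
    if not sites:
        raise AnalysisError("no eligible residues for NH vectors")
    vectors = np.empty((traj.n_frames, len(sites), 3))
    for f in range(traj.n_frames):
        xyz = traj.coordinates[f]
        for s, (n_i, h_i, ca_i, cprev_i) in enumerate(sites):
            if h_i >= 0:
                v = xyz[h_i] - xyz[n_i]
            else:
                h = amide_hydrogen(xyz[n_i], xyz[ca_i], xyz[cprev_i])
                v = h - xyz[n_i]
            vectors[f, s] = v / np.linalg.norm(v)
    return vectors


def p2_acf(vectors: np.ndarray, max_lag: int | None = None,
           dt_ps: float = 1.0) -> RCFSeries:
    """P2 autocorrelation averaged over all time origins and vectors.

    C(tau) = <P2(u(t) . u(t+tau))>.  Computed through the identity
    P2(u.v) = (3 sum_ab (u_a u_b)(v_a v_b) - 1)/2, which turns the average
    over origins into FFT-accelerated autocorrelations of the 6 unique
    components of the outer product u u^T.

    ``max_lag`` is in frames (default: half the trajectory, bounding
    estimator noise at long lags).
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim == 2:
        v = v[:, None, :]
    n_frames, n_vec, _ = v.shape
    if n_frames < 2:
        raise AnalysisError("need at least 2 frames")
    if max_lag is None:
        max_lag = n_frames // 2
    max_lag = int(min(max_lag, n_frames - 1))

    # unique outer-product components with multiplicity weights
    comps = [(0, 0, 1.0), (1, 1, 1.0), (2, 2, 1.0),
             (0, 1, 2.0), (0, 2, 2.0), (1, 2, 2.0)]
    nfft = 1 << int(np.ceil(np.log2(2 * n_frames)))
    acc = np.zeros(max_lag + 1)
    norm = n_frames - np.arange(max_lag + 1)
    for a, b, w in comps:
        series = v[:, :, a] * v[:, :, b]  # (frames, vectors)
        fft = np.fft.rfft(series, nfft, axis=0)
        corr = np.fft.irfft(fft * np.conj(fft), nfft, axis=0)[: max_lag + 1]
        acc += w * corr.sum(axis=1)
    values = (3.0 * acc / (norm * n_vec) - 1.0) / 2.0
    lags = np.arange(max_lag + 1) * dt_ps
    return RCFSeries(lags=lags, values=values, n_vectors=n_vec)


def fit_model_free(rcf: RCFSeries, fit_window: tuple[float, float] | None = None,
                   max_iter: int = 500, tol: float = 1e-8) -> ModelFreeFit:
    """Least-squares fit of y = a0 + (1 - a0) exp(-x/a1) to the RCF.

    Initialisation: a0 = last value in the window; a1 = the lag where the
    curve first falls below a0 + (1 - a0)/e.  A constant series is flagged
    degenerate (pure plateau, a1 unidentifiable).  Raises :class:`FitError`
    (carrying the best parameters) on non-convergence.
    """
    from scipy.optimize import least_squares

    x = np.asarray(rcf.lags, dtype=float)
    y = np.asarray(rcf.values, dtype=float)
    if fit_window is not None:
        mask = (x >= fit_window[0]) & (x <= fit_window[1])
        x, y = x[mask], y[mask]
    if x.size < 10:
        raise AnalysisError("fit window must contain at least 10 points")

    a0_init = float(y[-1])
    if np.ptp(y) < 1e-12:
        return ModelFreeFit(a0=a0_init, a1=np.inf, residual_norm=0.0,
                            degenerate=True)
    threshold = a0_init + (1.0 - a0_init) / np.e
    below = np.flatnonzero(y < threshold)
    a1_init = float(x[below[0]]) if below.size else float(x[-1] / 2.0)
    a1_init = max(a1_init, float(x[1] - x[0]))

    def model(p, xx):
        a0, a1 = p
        return a0 + (1.0 - a0) * np.exp(-xx / a1)

    sol = least_squares(lambda p: model(p, x) - y, x0=[a0_init, a1_init],
                        bounds=([-0.5, 1e-12], [1.0, np.inf]),
                        xtol=tol, ftol=tol, gtol=tol, max_nfev=max_iter * 4)
    if not sol.success:
        raise FitError("model-free fit did not converge", best_params=tuple(sol.x))
    a0, a1 = sol.x
    return ModelFreeFit(a0=float(a0), a1=float(a1),
                        residual_norm=float(np.linalg.norm(sol.fun)))


def rotational_stats(fit: ModelFreeFit, rcf: RCFSeries | None = None,
                     window_end: float | None = None) -> RotationalStats:
    """Correlation time tau_c and D_iso = 1/(6 tau_c) from a model-free fit.

    tau_c is the analytic integral of the fitted curve over [0, window_end]
    (default: the last RCF lag).  A finite window is required because the
    plateau term a0 > 0 makes the infinite integral diverge.
    """
    if window_end is None:
        if rcf is None:
            raise AnalysisError("need rcf or window_end")
        window_end = float(rcf.lags[-1])
    t = window_end
    if fit.degenerate or not np.isfinite(fit.a1):
        tau_c = fit.a0 * t
    else:
        tau_c = fit.a0 * t + (1.0 - fit.a0) * fit.a1 * (1.0 - np.exp(-t / fit.a1))
    if tau_c <= 0:
        raise AnalysisError(f"non-positive correlation time ({tau_c:.3g} ps)")
    return RotationalStats(tau_c=float(tau_c), d_iso=float(1.0 / (6.0 * tau_c)))
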