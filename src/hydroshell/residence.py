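"""Water residence times from survival probabilities.

For a shell (default 3.6 Å) around a residue selection, the continuous
survival probability S(t) is the fraction of waters present in the shell at a
time origin that remain in the shell at every frame up to lag t, averaged
over origins. The residence time τ is the trapezoidal integral of S(t) over
the sampled lags — the picosecond-scale quantity used to compare water
binding strength around (de)protonated residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import AtomRecord
from .trajectory import TrajectoryWindow, TrajectoryError

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCurve:
    """S(t) on a lag grid (ps). ``defined`` is false when no time origin ever
    had a water in the shell."""
    lags_ps: np.ndarray
    values: np.ndarray
    n_origins: int
    defined: bool = True


@dataclass
class ResidenceTime:
    residue: tuple[str, int, str] | str
    tau_ps: float
    window_values: list[float] = field(default_factory=list)


def _selection_predicate(selection) -> Callable[[AtomRecord], bool]:
    if callable(selection):
        return selection
    if isinstance(selection, str):
        return lambda a: a.residue_name == selection
    if isinstance(selection, tuple) and len(selection) == 2:
        chain, resid = selection
        return lambda a: a.chain_id == chain and a.residue_id == resid
    raise ValueError("selection must be a residue name, (chain, residue_id), "
                     "or a predicate on atoms")


def shell_membership(window: TrajectoryWindow, selection, cutoff: float) -> np.ndarray:
    """Boolean (n_frames, n_waters): water oxygen within ``cutoff`` of any
    selected residue heavy atom."""
    pred = _selection_predicate(selection)
    sel_idx = np.array([i for i, a in enumerate(window.topology.atoms)
                        if a.is_protein and not a.is_hydrogen and pred(a)],
                       dtype=int)
    if len(sel_idx) == 0:
        raise TrajectoryError("selection matches no protein residue")
    waters = window.water_indices
    inside = np.zeros((window.n_frames, len(waters)), dtype=bool)
    if len(waters) == 0:
        return inside
    for f in range(window.n_frames):
        sel_coords = window.coords[f][sel_idx]       # (n_sel, 3)
        wat_coords = window.coords[f][waters]        # (n_wat, 3)
        d2 = ((wat_coords[:, None, :] - sel_coords[None, :, :]) ** 2).sum(axis=2)
        inside[f] = (d2.min(axis=1) <= cutoff ** 2)
    return inside


def survival_probability(window: TrajectoryWindow, selection,
                         cutoff: float = 3.6,
                         max_lag_ps: float | None = None) -> SurvivalCurve:
    """Continuous survival probability of shell waters.

    S(t) = ⟨ N_continuous(t₀, t₀+t) / N(t₀) ⟩ over origins t₀ with N(t₀) > 0;
    a water that exits and re-enters does not survive. ``max_lag_ps`` defaults
    to half the window length to bound origin-count attrition.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    inside = shell_membership(window, selection, cutoff)
    n_frames = window.n_frames
    dt = window.frame_interval_ps
    if max_lag_ps is None:
        max_lag_frames = (n_frames - 1) // 2
    else:
        max_lag_frames = min(int(round(max_lag_ps / dt)), n_frames - 1)
    lags = np.arange(max_lag_frames + 1) * dt

    # run length of consecutive in-shell frames starting at each frame
    run = np.zeros_like(inside, dtype=int)
    if n_frames:
        run[-1] = inside[-1].astype(int)
        for f in range(n_frames - 2, -1, -1):
            run[f] = np.where(inside[f], run[f + 1] + 1, 0)

    origins = np.arange(n_frames - max_lag_frames)
    n_at_origin = inside[origins].sum(axis=1)
    valid = n_at_origin > 0
    if not valid.any():
        return SurvivalCurve(lags_ps=lags, values=np.full(len(lags), np.nan),
                             n_origins=0, defined=False)
    values = np.empty(len(lags))
    run_origins = run[origins][valid]          # (n_valid, n_waters)
    n_valid_origin = n_at_origin[valid].astype(float)
    for k in range(max_lag_frames + 1):
        surviving = (run_origins >= k + 1).sum(axis=1)
        values[k] = float(np.mean(surviving / n_valid_origin))
    return SurvivalCurve(lags_ps=lags, values=values,
                         n_origins=int(valid.sum()), defined=True)


def residence_time(curve: SurvivalCurve) -> float:
    """τ = trapezoidal integral of S over its lags (ps).

    An undefined curve propagates as NaN rather than a silent zero. When
    S(max lag) > 0.05 the value is a truncated lower bound; a warning is
    logged.
    """
    if not curve.defined:
        return float("nan")
    if curve.values[-1] > 0.05:
        logger.warning("survival probability is %.3f at the last lag (%.1f ps); "
                       "residence time is a truncated lower bound",
                       curve.values[-1], curve.lags_ps[-1])
    return float(np.trapezoid(curve.values, curve.lags_ps))


def residence_time_over_windows(windows: Sequence[TrajectoryWindow], selection,
                                cutoff: float = 3.6,
                                max_lag_ps: float | None = None,
                                label=None) -> ResidenceTime:
    """Residence time per window, averaged across windows."""
    taus = []
    for w in windows:
        curve = survival_probability(w, selection, cutoff=cutoff,
                                     max_lag_ps=max_lag_ps)
        taus.append(residence_time(curve))
    finite = [t for t in taus if np.isfinite(t)]
    mean_tau = float(np.mean(finite)) if finite else float("nan")
    return ResidenceTime(residue=label if label is not None else str(selection),
                         tau_ps=mean_tau, window_values=taus)
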