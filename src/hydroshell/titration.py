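"""Constant-pH titration analysis from λ-coordinate traces.

A λ coordinate interpolates between the protonated (λ≈0) and deprotonated
(λ≈1) states of a titratable residue. Samples below ``lambda_low`` count as
protonated, above ``lambda_high`` as deprotonated, and intermediates are
discarded. The deprotonation fraction per pH is fitted with a
Henderson–Hasselbalch/Hill curve

    S_deprot(pH) = 1 / (1 + 10^(n·(pKa − pH)))

to estimate the residue's pKa and Hill coefficient n.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

GROUP_LOW = "always_deprotonated"     # pKa in [2, 4)
GROUP_MID = "mid"                     # pKa in [4, 5)
GROUP_ANOMALOUS = "anomalous"         # pKa > 7
GROUP_UNCLASSIFIED = "unclassified"


class TitrationError(Exception):
    pass


@dataclass
class LambdaTrace:
    residue: str
    ph: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float).ravel()
        if self.samples.size < 1:
            raise TitrationError("λ trace must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise TitrationError("λ samples must be finite")


class DeprotonationFraction(NamedTuple):
    s_deprot: float          # NaN when undefined (no countable samples)
    n_prot: int
    n_deprot: int

    @property
    def defined(self) -> bool:
        return (self.n_prot + self.n_deprot) > 0


def deprotonation_fraction(samples, lambda_low: float = 0.2,
                           lambda_high: float = 0.8,
                           literal: bool = False) -> DeprotonationFraction:
    """Two-state counts and the deprotonation fraction of a λ trace.

    n_prot counts λ < lambda_low, n_deprot counts λ > lambda_high;
    intermediate samples are discarded. The default convention returns
    n_deprot/(n_prot + n_deprot), which rises with pH; ``literal=True``
    returns the complementary n_prot numerator. With no countable samples the
    fraction is NaN and flagged undefined.
    """
    lam = np.asarray(getattr(samples, "samples", samples), float).ravel()
    n_prot = int(np.count_nonzero(lam < lambda_low))
    n_deprot = int(np.count_nonzero(lam > lambda_high))
    total = n_prot + n_deprot
    if total == 0:
        return DeprotonationFraction(float("nan"), 0, 0)
    num = n_prot if literal else n_deprot
    return DeprotonationFraction(num / total, n_prot, n_deprot)


def hill_curve(ph, pka, hill_n):
    return 1.0 / (1.0 + 10.0 ** (hill_n * (pka - ph)))


@dataclass
class PKaFit:
    pka: float
    hill_n: float
    residual_norm: float
    converged: bool = True


def fit_pka(points: Sequence[tuple[float, float]],
            hill_bounds: tuple[float, float] = (0.2, 4.0)) -> PKaFit:
    """Least-squares Henderson–Hasselbalch/Hill fit of (pH, S_deprot) points.

    Initialized at the pH of the point nearest S = 0.5 with n = 1. Degenerate
    all-0 or all-1 data leave the pKa unbounded and are returned flagged
    rather than raised.
    """
    pts = [(p, s) for p, s in points if np.isfinite(s)]
    if len(pts) < 3:
        raise TitrationError(f"need ≥3 defined titration points, got {len(pts)}")
    ph = np.array([p for p, _ in pts], float)
    s = np.array([v for _, v in pts], float)
    if np.all(s <= 0.0) or np.all(s >= 1.0):
        return PKaFit(pka=float("nan"), hill_n=float("nan"),
                      residual_norm=float("nan"), converged=False)
    if s.min() > 0.5 or s.max() < 0.5:
        warnings.warn("titration points do not span both sides of the "
                      "transition; the pKa is an extrapolation", stacklevel=2)
    pka0 = float(ph[np.argmin(np.abs(s - 0.5))])
    lo, hi = ph.min(), ph.max()
    span = max(hi - lo, 1.0)
    try:
        popt, _ = curve_fit(hill_curve, ph, s, p0=[pka0, 1.0],
                            bounds=([lo - 2 * span, hill_bounds[0]],
                                    [hi + 2 * span, hill_bounds[1]]),
                            maxfev=10000)
    except RuntimeError as exc:
        raise TitrationError(f"pKa fit did not converge: {exc}") from exc
    resid = s - hill_curve(ph, *popt)
    return PKaFit(pka=float(popt[0]), hill_n=float(popt[1]),
                  residual_norm=float(np.linalg.norm(resid)))


@dataclass
class TitrationRecord:
    """Per-residue titration: (pH, S_deprot, n_prot, n_deprot) points plus the
    fitted pKa and Hill coefficient."""
    residue: str
    points: list[tuple[float, float, int, int]]
    pka: float = float("nan")
    hill_n: float = float("nan")

    def fit(self, **kwargs) -> PKaFit:
        fit = fit_pka([(p, s) for p, s, _, _ in self.points], **kwargs)
        self.pka, self.hill_n = fit.pka, fit.hill_n
        return fit


def titrate(traces: Sequence[LambdaTrace], lambda_low: float = 0.2,
            lambda_high: float = 0.8, literal: bool = False) -> list[TitrationRecord]:
    """Build per-residue titration records from λ traces and fit each pKa."""
    by_residue: dict[str, list[LambdaTrace]] = {}
    for t in traces:
        by_residue.setdefault(t.residue, []).append(t)
    records = []
    for residue in sorted(by_residue):
        pts = []
        for t in sorted(by_residue[residue], key=lambda t: t.ph):
            frac = deprotonation_fraction(t.samples, lambda_low, lambda_high,
                                          literal=literal)
            pts.append((t.ph, frac.s_deprot, frac.n_prot, frac.n_deprot))
        rec = TitrationRecord(residue=residue, points=pts)
        rec.fit()
        records.append(rec)
    return records


def classify_pka_groups(records: Sequence[TitrationRecord]
                        ) -> dict[str, list[str]]:
    """Bin residues by fitted pKa: [2, 4) always-deprotonated at the studied
    pH range, [4, 5) mid-transition, > 7 anomalous; anything else (including
    failed fits) is unclassified."""
    groups: dict[str, list[str]] = {GROUP_LOW: [], GROUP_MID: [],
                                    GROUP_ANOMALOUS: [], GROUP_UNCLASSIFIED: []}
    for r in records:
        if not np.isfinite(r.pka):
            groups[GROUP_UNCLASSIFIED].append(r.residue)
        elif 2.0 <= r.pka < 4.0:
            groups[GROUP_LOW].append(r.residue)
        elif 4.0 <= r.pka < 5.0:
            groups[GROUP_MID].append(r.residue)
        elif r.pka > 7.0:
            groups[GROUP_ANOMALOUS].append(r.residue)
        else:
            groups[GROUP_UNCLASSIFIED].append(r.residue)
    return groups


# ---------------------------------------------------------------------------
# Trace files
# ---------------------------------------------------------------------------

def read_lambda_trace(path: str | Path, residue: str, ph: float) -> LambdaTrace:
    """Read a two-column (time ps, λ) plain-text trace."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise TitrationError(f"{path}: expected two columns (time, λ)")
    return LambdaTrace(residue=residue, ph=ph, samples=data[:, 1])


def read_manifest(path: str | Path) -> list[LambdaTrace]:
    """Read a JSON manifest mapping residue → {pH: trace file} and load all
    traces (file paths are resolved relative to the manifest)."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    traces = []
    for residue, ph_map in manifest.items():
        for ph_str, rel in ph_map.items():
            traces.append(read_lambda_trace(path.parent / rel, residue,
                                            float(ph_str)))
    return traces
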