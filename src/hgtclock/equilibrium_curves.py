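"""Equilibrium curves relating GC3 to GC1 and GC2 across a genome ensemble.

Across bacteria and archaea, genome-wide GC1 and GC2 are smooth, saturating
functions of GC3: directional mutation pressure moves all three positions,
but first and second positions are damped by protein-level constraint. A
genome *at equilibrium* sits on these curves; recently transferred DNA does
not. Fitting f1: GC3 -> GC1 and f2: GC3 -> GC2 on an ensemble of genomes
gives the reference against which amelioration dating measures discrepancy.

Candidate forms are quadratic, cubic, and 4-parameter logistic; each is fit
by least squares and AIC selects among them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GenomePoint",
    "CurveModel",
    "fit_curves",
    "predict_gc12",
    "summarize_ensemble",
    "read_ensemble_tsv",
    "write_ensemble_tsv",
    "curves_to_json",
    "curves_from_json",
    "CURVE_FORMS",
]


@dataclass(frozen=True)
class GenomePoint:
    """Genome-wide pooled codon-position G+C for one genome."""

    genome_id: str
    gc1: float
    gc2: float
    gc3: float

    def __post_init__(self) -> None:
        for name in ("gc1", "gc2", "gc3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.genome_id}: {name}={v} outside [0,1]")


def _quadratic(x, a, b, c):
    return a + b * x + c * x**2


def _cubic(x, a, b, c, d):
    return a + b * x + c * x**2 + d * x**3


def _logistic4(x, lo, hi, x0, scale):
    return lo + (hi - lo) / (1.0 + np.exp(-(x - x0) / scale))


CURVE_FORMS: dict[str, tuple[Callable, list[float]]] = {
    "quadratic": (_quadratic, [0.3, 0.5, 0.0]),
    "cubic": (_cubic, [0.3, 0.5, 0.0, 0.0]),
    "logistic": (_logistic4, [0.3, 0.7, 0.5, 0.15]),
}

# RSS floor: on exactly noiseless data every nested form reaches machine-zero
# RSS and the AIC comparison reduces to the parameter-count penalty, so the
# most parsimonious form wins instead of floating-point noise deciding.
_RSS_FLOOR_PER_POINT = 1e-20


@dataclass(frozen=True)
class CurveModel:
    """One fitted GC3 -> GC1 (or GC2) curve.

    Predictions are clamped to [0,1]; ``gc3_range`` records the fitted
    support so out-of-range evaluation can be flagged.
    """

    target: str  # "GC1" | "GC2"
    form_id: str
    coefficients: tuple[float, ...]
    residual_sd: float
    n_points: int
    gc3_range: tuple[float, float]

    def predict(self, gc3: float | np.ndarray) -> np.ndarray | float:
        fn = CURVE_FORMS[self.form_id][0]
        raw = fn(np.asarray(gc3, dtype=float), *self.coefficients)
        clamped = np.clip(raw, 0.0, 1.0)
        if np.isscalar(gc3) or np.asarray(gc3).ndim == 0:
            return float(clamped)
        return clamped

    def __call__(self, gc3):
        return self.predict(gc3)


def _fit_one(
    target: str,
    x: np.ndarray,
    y: np.ndarray,
    candidates: dict[str, tuple[Callable, list[float]]],
) -> CurveModel:
    n = x.size
    best: tuple[float, CurveModel] | None = None
    for form_id, (fn, p0) in candidates.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(fn, x, y, p0=p0, maxfev=20000)
            resid = y - fn(x, *popt)
        except (RuntimeError, TypeError) as exc:
            warnings.warn(f"{target}: form {form_id} did not converge ({exc})")
            continue
        k = len(popt)
        rss = max(float(resid @ resid), n * _RSS_FLOOR_PER_POINT)
        aic = n * np.log(rss / n) + 2 * k
        dof = max(n - k, 1)
        model = CurveModel(
            target=target,
            form_id=form_id,
            coefficients=tuple(float(p) for p in popt),
            residual_sd=float(np.sqrt(rss / dof)),
            n_points=n,
            gc3_range=(float(x.min()), float(x.max())),
        )
        if best is None or aic < best[0]:
            best = (aic, model)
    if best is None:
        raise RuntimeError(f"{target}: no candidate form converged")
    return best[1]


def fit_curves(
    points: Sequence[GenomePoint],
    forms: Sequence[str] | None = None,
) -> tuple[CurveModel, CurveModel]:
    """Fit f1 (GC3->GC1) and f2 (GC3->GC2) over an ensemble of genomes.

    Requires >= 10 points spanning a GC3 range of at least 0.2 so the
    nonlinear forms are identifiable.
    """
    if len(points) < 10:
        raise ValueError("need >= 10 genome points to fit equilibrium curves")
    x = np.array([p.gc3 for p in points], dtype=float)
    if np.ptp(x) < 0.2:
        raise ValueError(
            f"GC3 span {np.ptp(x):.3f} < 0.2; design too narrow for curve fitting"
        )
    if forms is None:
        candidates = dict(CURVE_FORMS)
    else:
        unknown = set(forms) - set(CURVE_FORMS)
        if unknown:
            raise ValueError(f"unknown curve forms {sorted(unknown)}")
        candidates = {k: CURVE_FORMS[k] for k in forms}
    y1 = np.array([p.gc1 for p in points], dtype=float)
    y2 = np.array([p.gc2 for p in points], dtype=float)
    return _fit_one("GC1", x, y1, candidates), _fit_one("GC2", x, y2, candidates)


def predict_gc12(
    f1: CurveModel, f2: CurveModel, gc3: float
) -> tuple[float, float, bool]:
    """Predict (GC1, GC2) at a GC3 value; third element flags extrapolation."""
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"gc3={gc3} outside [0,1]")
    lo = min(f1.gc3_range[0], f2.gc3_range[0])
    hi = max(f1.gc3_range[1], f2.gc3_range[1])
    extrapolated = not (lo <= gc3 <= hi)
    return float(f1.predict(gc3)), float(f2.predict(gc3)), extrapolated


def summarize_ensemble(
    genomes: Sequence[tuple[str, Sequence]],
) -> list[GenomePoint]:
    """Pool per-CDS profiles into one GenomePoint per genome.

    ``genomes`` is a list of (genome_id, codon_sequences). Genomes with no
    CDS are skipped with a warning; duplicate ids are an error.
    """
    from .composition import codon_position_gc

    ids = [g[0] for g in genomes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate genome ids {dupes}")
    points = []
    for gid, seqs in genomes:
        seqs = list(seqs)
        if not seqs:
            warnings.warn(f"genome {gid}: no CDS, skipped")
            continue
        prof = codon_position_gc(seqs)
        points.append(GenomePoint(gid, prof.gc1, prof.gc2, prof.gc3))
    return points


def read_ensemble_tsv(path: str | Path) -> list[GenomePoint]:
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "gc1", "gc2", "gc3"}
    if not required.issubset(df.columns):
        raise ValueError(f"ensemble TSV must have columns {sorted(required)}")
    return [
        GenomePoint(str(r.genome_id), float(r.gc1), float(r.gc2), float(r.gc3))
        for r in df.itertuples()
    ]


def write_ensemble_tsv(points: Sequence[GenomePoint], path: str | Path) -> None:
    pd.DataFrame(
        [(p.genome_id, p.gc1, p.gc2, p.gc3) for p in points],
        columns=["genome_id", "gc1", "gc2", "gc3"],
    ).to_csv(path, sep="\t", index=False)


def curves_to_json(f1: CurveModel, f2: CurveModel, path: str | Path) -> None:
    doc = {}
    for m in (f1, f2):
        doc[m.target] = {
            "form_id": m.form_id,
            "coefficients": list(m.coefficients),
            "residual_sd": m.residual_sd,
            "n_points": m.n_points,
            "gc3_range": list(m.gc3_range),
        }
    Path(path).write_text(json.dumps(doc, indent=2))


def curves_from_json(path: str | Path) -> tuple[CurveModel, CurveModel]:
    doc = json.loads(Path(path).read_text())
    out = []
    for target in ("GC1", "GC2"):
        d = doc[target]
        out.append(
            CurveModel(
                target=target,
                form_id=d["form_id"],
                coefficients=tuple(d["coefficients"]),
                residual_sd=d["residual_sd"],
                n_points=d["n_points"],
                gc3_range=tuple(d["gc3_range"]),
            )
        )
    return out[0], out[1]
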