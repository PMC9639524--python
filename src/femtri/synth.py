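"""Synthetic study samples with the statistical structure of the three populations.

No individual-level femoral data were ever deposited for the three reference
samples (Egyptian, Indian, Greek), but the published per-group per-sex
summary statistics of the three inter-landmark distances — mean, SD, min,
max and cell sizes — fully parameterise a trivariate-normal emulator.  The
generator draws each (group, sex) cell from a multivariate normal with the
published means and SDs, a configurable inter-measurement correlation
(unpublished; default 0.5, moderate positive, reflecting shared body-size
scaling), and rejection-samples away any draw violating the strict triangle
inequality (or the optional published min/max truncation bounds), so every
emitted row passes geometry ingestion by construction.

The published CV and SDI columns are retained alongside the generator
parameters: they anchor the deterministic reproduction checks of the
statistics module.  The Greek SDI cells are flagged — they cannot be
recovered from the published Greek means by the M-referenced (or the
F-referenced) index and were likely computed on unrounded or subsampled
data; they are excluded from any reproduction check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PopulationModel",
    "GROUPS",
    "SEXES",
    "CELL_SIZES",
    "REFERENCE_SUMMARY",
    "default_models",
    "simulate_cell",
    "generate_study_sample",
]

GROUPS = ("Egyptian", "Greek", "Indian")
SEXES = ("F", "M")

#: published cell sizes: Egyptian 40M/61F, Indian 200M/80F, Greek 112M/91F (584 total)
CELL_SIZES: dict[tuple[str, str], int] = {
    ("Egyptian", "M"): 40, ("Egyptian", "F"): 61,
    ("Indian", "M"): 200, ("Indian", "F"): 80,
    ("Greek", "M"): 112, ("Greek", "F"): 91,
}

# Published summary table: per (measurement, group, sex) mean/SD/min/max plus
# the printed CV column and, per (measurement, group), the printed SDI.
# sdi_reproducible=False marks the Greek cells whose printed SDI does not
# follow from the printed means.
_REFERENCE_ROWS = [
    # measurement, group, sex, mean, sd, min, max, cv, sdi, sdi_reproducible
    ("ab_mm", "Egyptian", "F", 26.80, 3.71, 19.00, 40.00, 13.8, 8.99, True),
    ("ab_mm", "Egyptian", "M", 29.45, 5.13, 14.00, 41.00, 17.4, 8.99, True),
    ("ab_mm", "Greek", "F", 29.69, 5.59, 18.52, 59.83, 18.8, 4.21, False),
    ("ab_mm", "Greek", "M", 30.25, 5.56, 16.67, 45.93, 18.4, 4.21, False),
    ("ab_mm", "Indian", "F", 30.15, 4.47, 21.80, 42.15, 14.8, 9.02, True),
    ("ab_mm", "Indian", "M", 33.14, 5.31, 18.00, 48.00, 16.02, 9.02, True),
    ("ab_mm", "Pooled", "F", 29.09, 4.95, 18.52, 59.83, 17.01, 8.52, True),
    ("ab_mm", "Pooled", "M", 31.80, 5.58, 14.00, 48.00, 17.55, 8.52, True),
    ("bc_mm", "Egyptian", "F", 55.11, 4.34, 40.00, 65.00, 7.87, 11.18, True),
    ("bc_mm", "Egyptian", "M", 62.05, 5.66, 50.00, 76.00, 9.12, 11.18, True),
    ("bc_mm", "Greek", "F", 53.26, 4.79, 42.13, 67.19, 8.99, 10.46, False),
    ("bc_mm", "Greek", "M", 59.38, 5.20, 47.14, 71.73, 8.76, 10.46, False),
    ("bc_mm", "Indian", "F", 51.74, 5.51, 41.00, 63.15, 10.65, 13.84, True),
    ("bc_mm", "Indian", "M", 60.05, 4.75, 49.60, 79.00, 7.91, 13.84, True),
    ("bc_mm", "Pooled", "F", 53.22, 5.09, 40.00, 67.19, 9.56, 11.39, True),
    ("bc_mm", "Pooled", "M", 60.06, 5.05, 47.14, 79.00, 8.41, 11.39, True),
    ("ac_mm", "Egyptian", "F", 37.90, 4.86, 27.00, 57.00, 12.82, 9.44, True),
    ("ac_mm", "Egyptian", "M", 41.85, 5.60, 29.00, 58.00, 13.38, 9.44, True),
    ("ac_mm", "Greek", "F", 45.06, 5.44, 24.89, 59.34, 12.07, 11.62, False),
    ("ac_mm", "Greek", "M", 51.55, 6.71, 36.66, 71.71, 13.02, 11.62, False),
    ("ac_mm", "Indian", "F", 40.14, 4.39, 27.60, 47.90, 10.94, 18.92, True),
    ("ac_mm", "Indian", "M", 49.51, 5.70, 36.10, 65.15, 11.51, 18.92, True),
    ("ac_mm", "Pooled", "F", 41.48, 5.77, 24.89, 59.34, 13.91, 15.84, True),
    ("ac_mm", "Pooled", "M", 49.29, 6.64, 29.00, 71.71, 13.47, 15.84, True),
]

REFERENCE_SUMMARY = pd.DataFrame(
    _REFERENCE_ROWS,
    columns=["measurement", "group", "sex", "mean", "sd", "min", "max",
             "cv_published", "sdi_published", "sdi_reproducible"],
)


@dataclass
class PopulationModel:
    """Generator parameters for one (group, sex) cell.

    Means/SDs are per measurement in AB, BC, AC order (mm); ``corr`` is the
    3x3 inter-measurement correlation matrix; ``bounds`` optionally truncates
    each measurement to a (min, max) window via rejection.
    """

    group: str
    sex: str
    means_mm: np.ndarray
    sds_mm: np.ndarray
    corr: np.ndarray
    n: int
    bounds: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.means_mm = np.asarray(self.means_mm, dtype=float)
        self.sds_mm = np.asarray(self.sds_mm, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.means_mm.shape != (3,) or self.sds_mm.shape != (3,):
            raise ValueError("means and sds must each have three entries (AB, BC, AC)")
        if (self.sds_mm <= 0).any():
            raise ValueError("SDs must be positive")
        if self.n < 1:
            raise ValueError("cell size must be >= 1")
        if self.corr.shape != (3, 3) or not np.allclose(self.corr, self.corr.T):
            raise ValueError("corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("corr must have unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() <= 0:
            raise ValueError("corr must be positive definite")

    @property
    def covariance(self) -> np.ndarray:
        return self.corr * np.outer(self.sds_mm, self.sds_mm)


def default_models(
    corr_off_diagonal: float = 0.5,
    truncate: bool = False,
) -> list[PopulationModel]:
    """The six published (group, sex) cells as generator models.

    Means, SDs and (optional) truncation bounds come verbatim from the
    published summary table; cell sizes from the published sample
    description.  The inter-measurement correlation was never published:
    the default 0.5 off-diagonal is a configuration surface, and no
    reproduction check depends on its value.  Truncation to the published
    min/max windows is off by default because it would bias the realised
    means/SDs away from the published parameters.
    """
    corr = np.full((3, 3), corr_off_diagonal, dtype=float)
    np.fill_diagonal(corr, 1.0)
    models = []
    for group in GROUPS:
        for sex in SEXES:
            cell = REFERENCE_SUMMARY[
                (REFERENCE_SUMMARY["group"] == group) & (REFERENCE_SUMMARY["sex"] == sex)
            ].set_index("measurement")
            means = cell.loc[["ab_mm", "bc_mm", "ac_mm"], "mean"].to_numpy()
            sds = cell.loc[["ab_mm", "bc_mm", "ac_mm"], "sd"].to_numpy()
            bounds = None
            if truncate:
                bounds = {
                    m: (float(cell.loc[m, "min"]), float(cell.loc[m, "max"]))
                    for m in ("ab_mm", "bc_mm", "ac_mm")
                }
            models.append(PopulationModel(
                group=group, sex=sex, means_mm=means, sds_mm=sds,
                corr=corr.copy(), n=CELL_SIZES[(group, sex)], bounds=bounds,
            ))
    return models


def _row_valid(row: np.ndarray, bounds: dict[str, tuple[float, float]] | None) -> bool:
    ab, bc, ac = row
    if not (ab > 0 and bc > 0 and ac > 0):
        return False
    if not (ab + bc > ac and ab + ac > bc and bc + ac > ab):
        return False
    if bounds is not None:
        for value, key in zip(row, ("ab_mm", "bc_mm", "ac_mm")):
            lo, hi = bounds[key]
            if not (lo <= value <= hi):
                return False
    return True


def simulate_cell(
    model: PopulationModel,
    seed: int | np.random.Generator = 0,
    n: int | None = None,
) -> pd.DataFrame:
    """Draw one cell's measurement rows by trivariate-normal rejection sampling.

    Rows violating the strict triangle inequality (or the truncation bounds,
    if set) are redrawn; the rejection count is recorded in the frame's
    ``attrs["n_rejected"]``.  Aborts if the acceptance rate falls below 1%.
    Deterministic per seed; ``n`` overrides the model's cell size (used for
    scaled-up parameter-recovery checks).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target = model.n if n is None else int(n)
    accepted: list[np.ndarray] = []
    n_rejected = 0
    n_drawn = 0
    while sum(len(a) for a in accepted) < target:
        batch = max(64, target)
        draws = rng.multivariate_normal(model.means_mm, model.covariance, size=batch)
        keep = np.array([_row_valid(row, model.bounds) for row in draws])
        n_drawn += batch
        n_rejected += int((~keep).sum())
        accepted.append(draws[keep])
        if n_drawn >= 100 * target and sum(len(a) for a in accepted) < 0.01 * n_drawn:
            raise RuntimeError(
                f"rejection rate above 99% for cell {model.group}/{model.sex}; "
                "constraints are unattainable under these parameters"
            )
    rows = np.vstack(accepted)[:target]
    frame = pd.DataFrame(rows, columns=["ab_mm", "bc_mm", "ac_mm"])
    frame.insert(0, "sex", model.sex)
    frame.insert(0, "group", model.group)
    frame.attrs["n_rejected"] = n_rejected
    return frame


def generate_study_sample(
    models: list[PopulationModel] | None = None,
    seed: int = 0,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Full labelled synthetic study sample (584 rows with the default cells).

    Cells are concatenated with group/sex labels, sequential ids and
    side="L".  ``scale`` multiplies every cell size (e.g. 50 for
    convergence checks).  Column schema: id, group, sex, side, ab_mm,
    bc_mm, ac_mm.
    """
    if models is None:
        models = default_models()
    rng = np.random.default_rng(seed)
    frames = []
    for model in models:
        n = max(1, int(round(model.n * scale)))
        frames.append(simulate_cell(model, seed=rng, n=n))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "id", [f"S{i:05d}" for i in range(1, len(table) + 1)])
    table.insert(3, "side", "L")
    return table[["id", "group", "sex", "side", "ab_mm", "bc_mm", "ac_mm"]]
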