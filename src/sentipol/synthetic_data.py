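"""Generation, I/O and binning of bivariate sentiment-score datasets.

A dataset is a timestamped sequence of score pairs (w+, w-) in [0,1]^2, one
per post, optionally labelled by group chat.  This module can

* generate synthetic corpora with known ground truth — either by sampling the
  two axes independently from stationary Beta mixtures, by interpolating
  mixture parameters linearly in time between an initial and a final spec
  (emulating an evolving opinion climate), or by sampling from any
  cell-averaged 2-D density (e.g. a solver snapshot);
* read and write delimited text with configurable column names;
* bin a time window of records onto a uniform grid as a probability density
  and extract its marginals and means.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .equilibria import BetaMixtureSpec, BetaSpec
from .grids import DensityField2D, Grid2D, Marginal1D

__all__ = [
    "SentimentDataset",
    "MixturePair",
    "generate_synthetic_dataset",
    "read_sentiment_csv",
    "bin_to_density",
    "empirical_marginals",
    "sample_from_field",
    "save_density",
    "load_density",
]

DEFAULT_COLUMNS = {"t": "t", "w_plus": "w_plus", "w_minus": "w_minus", "group": "group"}


class MixturePair(NamedTuple):
    """Ground-truth marginal mixtures for the two score axes."""

    positive: BetaMixtureSpec
    negative: BetaMixtureSpec


@dataclass
class SentimentDataset:
    """Timestamped score pairs, held as a DataFrame with columns
    ``t, w_plus, w_minus, group`` and sorted by time."""

    records: pd.DataFrame
    t_span: tuple[float, float]

    def __post_init__(self) -> None:
        required = {"t", "w_plus", "w_minus"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset is missing columns {sorted(missing)}")
        if "group" not in self.records.columns:
            self.records["group"] = pd.NA
        if len(self.records):
            t = self.records["t"].to_numpy(dtype=float)
            if not np.all(np.isfinite(t)):
                raise ValueError("record times must be finite")
            t0, t1 = self.t_span
            if t.min() < t0 - 1e-12 or t.max() > t1 + 1e-12:
                raise ValueError("record times fall outside t_span")
            for col in ("w_plus", "w_minus"):
                w = self.records[col].to_numpy(dtype=float)
                if np.any((w < 0.0) | (w > 1.0)):
                    raise ValueError(f"{col} scores must lie in [0, 1]")
            self.records = self.records.sort_values("t", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path, columns: dict[str, str] | None = None) -> None:
        mapping = {**DEFAULT_COLUMNS, **(columns or {})}
        out = self.records.rename(columns=mapping)
        out.to_csv(path, index=False)


def _interp_spec(s0: BetaSpec, s1: BetaSpec, s: float) -> BetaSpec:
    return BetaSpec(m=(1 - s) * s0.m + s * s1.m, mu=(1 - s) * s0.mu + s * s1.mu)


def _interp_mixture(m0: BetaMixtureSpec, m1: BetaMixtureSpec, s: float) -> BetaMixtureSpec:
    return BetaMixtureSpec(
        weight_S=(1 - s) * m0.weight_S + s * m1.weight_S,
        spec_S=_interp_spec(m0.spec_S, m1.spec_S, s),
        spec_R=_interp_spec(m0.spec_R, m1.spec_R, s),
    )


def _sample_mixture(mix: BetaMixtureSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    pick_s = rng.random(size) < mix.weight_S
    out = np.empty(size)
    for spec, mask in ((mix.spec_S, pick_s), (mix.spec_R, ~pick_s)):
        k = int(mask.sum())
        if k:
            out[mask] = rng.beta(spec.a, spec.b, size=k)
    return out


def generate_synthetic_dataset(
    truth: MixturePair | tuple[MixturePair, MixturePair] | DensityField2D,
    n_posts: int,
    t_span: tuple[float, float] = (0.0, 191.0),
    seed: int = 0,
    groups: int | list[str] = 6,
    times: np.ndarray | None = None,
) -> SentimentDataset:
    """Draw ``n_posts`` timestamped score pairs from a known ground truth.

    ``truth`` may be a :class:`MixturePair` (stationary sampling), a pair
    ``(initial, final)`` of MixturePairs whose parameters are interpolated
    linearly over ``t_span`` (each record is drawn from the mixture at its own
    time), or a :class:`DensityField2D` snapshot.  Post times are i.i.d.
    uniform on ``t_span`` unless an explicit ``times`` schedule is given.
    """
    if n_posts < 0:
        raise ValueError("n_posts must be nonnegative")
    rng = np.random.default_rng(seed)
    t0, t1 = t_span
    if times is None:
        times = np.sort(rng.uniform(t0, t1, size=n_posts))
    else:
        times = np.sort(np.asarray(times, dtype=float))
        if times.size != n_posts:
            raise ValueError("times schedule length must equal n_posts")

    if isinstance(truth, DensityField2D):
        w = sample_from_field(truth, n_posts, rng)
        w_plus, w_minus = w[:, 0], w[:, 1]
    elif isinstance(truth, MixturePair):
        w_plus = _sample_mixture(truth.positive, rng, n_posts)
        w_minus = _sample_mixture(truth.negative, rng, n_posts)
    else:
        initial, final = truth
        frac = (times - t0) / (t1 - t0) if t1 > t0 else np.zeros_like(times)
        w_plus = np.empty(n_posts)
        w_minus = np.empty(n_posts)
        for i, s in enumerate(frac):
            w_plus[i] = _sample_mixture(_interp_mixture(initial.positive, final.positive, s), rng, 1)[0]
            w_minus[i] = _sample_mixture(_interp_mixture(initial.negative, final.negative, s), rng, 1)[0]

    if isinstance(groups, int):
        labels = [f"chat_{k}" for k in range(groups)]
    else:
        labels = list(groups)
    group_col = rng.choice(labels, size=n_posts) if labels and n_posts else []
    df = pd.DataFrame({"t": times, "w_plus": w_plus, "w_minus": w_minus, "group": group_col})
    return SentimentDataset(df, t_span=t_span)


def read_sentiment_csv(
    path: str | Path,
    columns: dict[str, str] | None = None,
    strict: bool = True,
    delimiter: str = ",",
    t_span: tuple[float, float] | None = None,
) -> SentimentDataset:
    """Read an S1-shaped delimited file into a dataset.

    ``columns`` maps logical names (t, w_plus, w_minus, group) to header names.
    Rows with scores outside [0, 1] raise (strict mode, naming the row) or are
    dropped with a warning.
    """
    mapping = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, delimiter=delimiter)
    inverse = {v: k for k, v in mapping.items()}
    missing = [mapping[k] for k in ("t", "w_plus", "w_minus") if mapping[k] not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.rename(columns=inverse)
    keep = [c for c in ("t", "w_plus", "w_minus", "group") if c in df.columns]
    df = df[keep]
    for col in ("t", "w_plus", "w_minus"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(f"{path}: malformed {col} value at data row {int(bad.idxmax()) + 1}")
        df[col] = coerced
    out_of_range = (
        (df["w_plus"] < 0) | (df["w_plus"] > 1) | (df["w_minus"] < 0) | (df["w_minus"] > 1)
    )
    if out_of_range.any():
        rows = (df.index[out_of_range] + 1).tolist()
        if strict:
            raise ValueError(f"{path}: score outside [0, 1] at data row(s) {rows}")
        import warnings

        warnings.warn(f"{path}: dropping {len(rows)} row(s) with scores outside [0, 1]")
        df = df[~out_of_range]
    df = df.dropna(subset=["t", "w_plus", "w_minus"]).reset_index(drop=True)
    if t_span is None:
        if len(df):
            t_span = (float(df["t"].min()), float(df["t"].max()))
        else:
            t_span = (0.0, 0.0)
    return SentimentDataset(df, t_span=t_span)


def bin_to_density(
    dataset: SentimentDataset,
    grid: Grid2D | None = None,
    window: tuple[float, float] | None = None,
) -> DensityField2D:
    """Histogram the records with times in ``window`` into a probability density.

    Cell counts are divided by ``N_window * dw+ * dw-`` so the field has unit
    mass whenever the window holds at least one record; an empty window gives
    a zero-mass field (never NaN).  Scores of exactly 1.0 land in the last cell.
    """
    grid = grid or Grid2D()
    if window is None:
        window = dataset.t_span
    lo, hi = window
    if hi < lo:
        raise ValueError("window must be nonempty")
    t = dataset.records["t"].to_numpy(dtype=float)
    mask = (t >= lo) & (t <= hi)
    n = int(mask.sum())
    values = np.zeros((grid.n_plus, grid.n_minus))
    if n:
        i = grid.axis_plus.locate(dataset.records["w_plus"].to_numpy(dtype=float)[mask])
        j = grid.axis_minus.locate(dataset.records["w_minus"].to_numpy(dtype=float)[mask])
        np.add.at(values, (i, j), 1.0)
        values /= n * grid.cell_area
    return DensityField2D(grid, values)


class Marginals(NamedTuple):
    g_plus: Marginal1D
    h_minus: Marginal1D
    m_plus: float
    m_minus: float


def empirical_marginals(field: DensityField2D) -> Marginals:
    """Unit-mass marginals of a 2-D density and its density-weighted means."""
    if field.mass <= 0.0:
        raise ValueError("marginals undefined for a zero-mass field")
    g = field.marginal_plus().normalized()
    h = field.marginal_minus().normalized()
    return Marginals(g, h, g.mean, h.mean)


def sample_from_field(field: DensityField2D, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` score pairs from a cell-averaged density (uniform within cells)."""
    if field.mass <= 0.0:
        raise ValueError("cannot sample from a zero-mass field")
    p = field.values.ravel() / field.values.sum()
    cells = rng.choice(p.size, size=n, p=p)
    i, j = np.unravel_index(cells, field.values.shape)
    u = rng.random((n, 2))
    w_plus = (i + u[:, 0]) * field.grid.dw_plus
    w_minus = (j + u[:, 1]) * field.grid.dw_minus
    return np.column_stack([w_plus, w_minus])


def save_density(field: DensityField2D, path: str | Path, t: float | None = None) -> None:
    """Write a density as a CSV matrix plus a JSON sidecar with the grid spec."""
    path = Path(path)
    np.savetxt(path, field.values, delimiter=",")
    sidecar = {
        "n_plus": field.grid.n_plus,
        "n_minus": field.grid.n_minus,
        "mass": field.mass,
        "time": t,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_density(path: str | Path) -> DensityField2D:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DensityField2D(Grid2D(meta["n_plus"], meta["n_minus"]), values)
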