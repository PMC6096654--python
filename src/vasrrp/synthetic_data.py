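"""Synthetic response data in three formats: VAS-RRP, Likert, ranking.

Continuous item responses are drawn from the factor model
``x = Lambda xi + eps`` with standard-normal latent traits and normal
residuals (correlated within testlets in CTCU mode), then clipped to
[-3, 3].  The continuous responses are rendered as

* VAS-RRP scores -- the linear map onto [0, 1] (positions on a response
  continuum whose endpoints sit at -3 and +3);
* Likert categories -- bucketing at fixed cut points, coded 1..k;
* within-testlet ranks -- ipsative order statistics, 1 (lowest) to L
  (highest) inside each respondent x testlet block.

Datasets round-trip through CSV with a sidecar JSON carrying the spec,
seed and format metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .factor_model import FactorModelSpec, residual_covariance

__all__ = [
    "ContinuousDataset",
    "FormattedDataset",
    "generate_dataset",
    "to_vasrrp",
    "to_likert",
    "to_ranking",
    "vas_item_score",
    "rescale_common",
    "write_dataset",
    "read_dataset",
]

#: Continuous responses are restricted to this range before formatting.
VALUE_RANGE = (-3.0, 3.0)

#: Standard cut-point grids: two 3-point and two 5-point Likert scales.
CUT_POINT_SETS = {
    "{-2,2}": (-2.0, 2.0),
    "{-1,1}": (-1.0, 1.0),
    "{-3,-1,1,3}": (-3.0, -1.0, 1.0, 3.0),
    "{-1.5,-0.5,0.5,1.5}": (-1.5, -0.5, 0.5, 1.5),
}


def item_labels(spec: FactorModelSpec) -> list[str]:
    """Column labels of the form T<testlet>_L<latent>, 1-based."""
    return [
        f"T{t + 1}_L{l + 1}"
        for t, l in zip(spec.item_to_testlet, spec.item_to_latent)
    ]


@dataclass
class ContinuousDataset:
    """n x p continuous responses plus the generating metadata.

    Columns are ordered as in the spec (grouped by latent trait).
    ``clip_fraction`` records the share of raw draws that fell outside
    [-3, 3] and were clipped.
    """

    values: np.ndarray
    spec: FactorModelSpec
    seed: int
    clip_fraction: float = 0.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def labels(self) -> list[str]:
        return item_labels(self.spec)


@dataclass
class FormattedDataset:
    """Responses rendered in one response format."""

    values: np.ndarray
    format: str  # "vasrrp" | "likert" | "ranking"
    spec: FactorModelSpec
    seed: int
    cut_points: tuple | None = None
    rescaled: bool = field(default=False)

    @property
    def n_categories(self) -> int | None:
        if self.format != "likert" or self.cut_points is None:
            return None
        return len(self.cut_points) + 1

    @property
    def labels(self) -> list[str]:
        return item_labels(self.spec)


def generate_dataset(
    spec: FactorModelSpec, n: int, seed: int, clip: bool = True
) -> ContinuousDataset:
    """Draw n independent respondents from the generating model.

    Rows are ``x = Lambda xi + eps`` with ``xi ~ N(0, Phi)`` and
    ``eps ~ N(0, Theta)``; values are clipped to [-3, 3] afterwards
    (disable with ``clip=False`` to inspect the raw normal draws).
    Identical (spec, n, seed) gives identical output.
    """
    if n < 2:
        raise ValueError("need at least two respondents")
    rng = np.random.default_rng(seed)
    Theta = residual_covariance(spec)
    try:
        chol_phi = np.linalg.cholesky(spec.latent_corr)
        chol_theta = np.linalg.cholesky(Theta)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validate()
        raise ValueError("generating covariance is not positive definite") from exc
    xi = rng.standard_normal((n, spec.n_latents)) @ chol_phi.T
    eps = rng.standard_normal((n, spec.n_items)) @ chol_theta.T
    x = xi @ spec.lambda_matrix.T + eps
    lo, hi = VALUE_RANGE
    clipped = float(np.mean((x < lo) | (x > hi)))
    if clip:
        np.clip(x, lo, hi, out=x)
    return ContinuousDataset(values=x, spec=spec, seed=seed, clip_fraction=clipped)


def to_vasrrp(dataset: ContinuousDataset) -> FormattedDataset:
    """Map continuous responses in [-3, 3] linearly onto [0, 1]."""
    lo, hi = VALUE_RANGE
    v = dataset.values
    if v.min() < lo or v.max() > hi:
        raise ValueError("continuous values outside [-3, 3]; clip upstream")
    return FormattedDataset(
        values=(v - lo) / (hi - lo),
        format="vasrrp",
        spec=dataset.spec,
        seed=dataset.seed,
    )


def to_likert(dataset: ContinuousDataset, cut_points) -> FormattedDataset:
    """Bucket continuous responses at fixed cut points, categories 1..k.

    A value v falls in category ``1 + #{c : v > c}``, so the k = len(cuts)+1
    categories partition the line at the cuts.
    """
    cuts = np.asarray(cut_points, float)
    if cuts.size == 0:
        raise ValueError("need at least one cut point")
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("cut points must be strictly ascending")
    cat = 1 + (dataset.values[:, :, None] > cuts[None, None, :]).sum(axis=2)
    return FormattedDataset(
        values=cat.astype(np.int64),
        format="likert",
        spec=dataset.spec,
        seed=dataset.seed,
        cut_points=tuple(cuts.tolist()),
    )


def to_ranking(dataset) -> FormattedDataset:
    """Rank each respondent's items within each testlet.

    The smallest value in a testlet receives rank 1 and the largest rank L,
    so rank scores correlate positively with the underlying trait.  Ties
    (probability zero for continuous input) break by ascending item index.
    The per-respondent rank sum inside a testlet is the constant L(L+1)/2.
    """
    spec = dataset.spec
    v = dataset.values
    ranks = np.empty_like(v, dtype=np.int64)
    for t in range(spec.n_testlets):
        idx = np.flatnonzero(spec.item_to_testlet == t)
        if idx.size < 2:
            raise ValueError("ranking needs testlets of at least two items")
        block = v[:, idx]
        order = np.argsort(block, axis=1, kind="stable")
        rk = np.empty_like(order)
        np.put_along_axis(rk, order, np.arange(1, idx.size + 1)[None, :], axis=1)
        ranks[:, idx] = rk
    return FormattedDataset(
        values=ranks, format="ranking", spec=spec, seed=dataset.seed
    )


def vas_item_score(x1: float, x2: float, x3: float) -> float:
    """Score of a mark at coordinate x3 on a continuum with endpoints x1, x2.

    Returns (x3 - x1) / (x2 - x1), the relative position in [0, 1].
    Coordinates are screen pixels, so any common offset cancels.
    """
    if x1 == x2:
        raise ValueError("degenerate scale: endpoints coincide")
    score = (x3 - x1) / (x2 - x1)
    if not 0.0 <= score <= 1.0:
        raise ValueError("mark lies outside the scale endpoints")
    return score


def rescale_common(data: FormattedDataset) -> FormattedDataset:
    """Bring any format onto a common (0, 1] range for bias comparison.

    Likert categories are divided by the number of categories, ranks by the
    number of items per testlet; VAS-RRP scores are already on [0, 1].
    """
    if data.format == "vasrrp":
        return data
    if data.format == "likert":
        divisor = data.n_categories
    elif data.format == "ranking":
        divisor = data.spec.n_latents
    else:
        raise ValueError(f"unknown format {data.format!r}")
    return FormattedDataset(
        values=data.values / divisor,
        format=data.format,
        spec=data.spec,
        seed=data.seed,
        cut_points=data.cut_points,
        rescaled=True,
    )


# -- CSV round trip --------------------------------------------------------

def write_dataset(dataset, path) -> None:
    """Write values as CSV (one row per respondent) plus a sidecar JSON
    (same stem, ``.meta.json``) with spec, seed and format metadata."""
    path = Path(path)
    df = pd.DataFrame(dataset.values, columns=item_labels(dataset.spec))
    df.to_csv(path, index=False)
    meta = {"spec": dataset.spec.to_dict(), "seed": dataset.seed}
    if isinstance(dataset, FormattedDataset):
        meta["format"] = dataset.format
        meta["cut_points"] = list(dataset.cut_points) if dataset.cut_points else None
        meta["rescaled"] = dataset.rescaled
    else:
        meta["format"] = "continuous"
        meta["clip_fraction"] = dataset.clip_fraction
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_dataset(path):
    """Inverse of :func:`write_dataset`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    spec = FactorModelSpec.from_dict(meta["spec"])
    values = pd.read_csv(path).to_numpy()
    if meta["format"] == "continuous":
        return ContinuousDataset(
            values=values,
            spec=spec,
            seed=meta["seed"],
            clip_fraction=meta.get("clip_fraction", 0.0),
        )
    if meta["format"] in ("likert", "ranking") and not meta.get("rescaled"):
        values = values.astype(np.int64)
    return FormattedDataset(
        values=values,
        format=meta["format"],
        spec=spec,
        seed=meta["seed"],
        cut_points=tuple(meta["cut_points"]) if meta.get("cut_points") else None,
        rescaled=meta.get("rescaled", False),
    )
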