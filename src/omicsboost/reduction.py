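"""PCA reduction of selected continuous blocks into a unified design matrix.

Each continuous block's selected features are centred and projected onto
their leading principal components (T_L = X W_L, default L = 2 per block);
selected discrete features pass through unchanged.  Inputs are assumed
already normalised (median-centred, log2), so the default is centring
without unit-variance scaling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MultiOmicsCohort
from .selection import SelectionReport

logger = logging.getLogger(__name__)


@dataclass
class PcaTransform:
    """Fitted per-block PCA: orthonormal loadings, centres and explained
    variance fractions (non-increasing)."""

    block: str
    feature_ids: list[str]
    centers: np.ndarray          # (F,)
    loadings: np.ndarray         # (F, L), orthonormal columns
    explained_variance_ratio: np.ndarray  # (L,)
    scales: np.ndarray | None = None      # (F,) if unit-variance scaling used

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = X - self.centers
        if self.scales is not None:
            Z = Z / self.scales
        return Z @ self.loadings

    def to_json(self, path: str | Path) -> None:
        payload = {
            "block": self.block,
            "feature_ids": self.feature_ids,
            "centers": self.centers.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "scales": None if self.scales is None else self.scales.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["block"],
            d["feature_ids"],
            np.asarray(d["centers"]),
            np.asarray(d["loadings"]),
            np.asarray(d["explained_variance_ratio"]),
            None if d["scales"] is None else np.asarray(d["scales"]),
        )


def fit_pca(
    X: np.ndarray, L: int, block: str = "", feature_ids=None, scale: bool = False
) -> PcaTransform:
    """Fit an L-component PCA on a samples x features matrix.

    Components are ordered by decreasing variance; each loading column is
    signed so its largest-magnitude element is positive, making outputs
    reproducible across linear-algebra backends.  Requesting more
    components than the data's rank raises with the attainable maximum.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca requires a 2-D matrix with >= 2 samples")
    n, p = X.shape
    max_l = min(n - 1, p)
    if not 1 <= L <= max_l:
        raise ValueError(f"L={L} out of range; attainable L: 1..{max_l}")
    centers = X.mean(axis=0)
    Z = X - centers
    scales = None
    if scale:
        scales = Z.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        Z = Z / scales
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s[0] > 0 else 0
    if L > rank:
        raise ValueError(f"L={L} exceeds data rank; attainable L: 1..{max(rank, 0)}")
    loadings = vt[:L].T.copy()
    # sign convention: largest-|.| element of each component positive
    for j in range(L):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    var = s**2
    evr = var[:L] / var.sum()
    return PcaTransform(
        block,
        list(feature_ids) if feature_ids is not None else [f"x{j}" for j in range(p)],
        centers,
        loadings,
        evr,
        scales,
    )


@dataclass
class ReducedDataset:
    """Unified post-selection, post-PCA design matrix.

    ``X`` is a samples x columns DataFrame; ``roles`` maps each column to
    ``("passthrough", block)`` or ``("pc", block)``; ``transforms`` holds
    the fitted per-block PCA objects.
    """

    X: pd.DataFrame
    y: np.ndarray
    roles: dict[str, tuple[str, str]]
    transforms: dict[str, PcaTransform] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    @property
    def passthrough_columns(self) -> list[str]:
        return [c for c, (role, _) in self.roles.items() if role == "passthrough"]

    @property
    def pc_columns(self) -> list[str]:
        return [c for c, (role, _) in self.roles.items() if role == "pc"]

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        out.insert(0, "sample_id", self.sample_ids or list(self.X.index))
        out.insert(1, "label", self.y)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, roles: dict | None = None) -> "ReducedDataset":
        df = pd.read_csv(path)
        sample_ids = df["sample_id"].astype(str).tolist()
        y = df["label"].to_numpy(dtype=int)
        X = df.drop(columns=["sample_id", "label"])
        X.index = pd.Index(sample_ids, name="sample_id")
        if roles is None:
            roles = {
                c: (("pc", c.rsplit("_PC", 1)[0]) if "_PC" in c else ("passthrough", ""))
                for c in X.columns
            }
        return cls(X, y, roles, sample_ids=sample_ids)


def assemble_design(
    cohort: MultiOmicsCohort,
    selection: SelectionReport,
    L_per_block: int = 2,
    scale: bool = False,
) -> ReducedDataset:
    """Build the unified design matrix from a labelled cohort.

    Selected discrete features pass through unchanged; every continuous
    block is reduced independently to its first ``L_per_block`` components
    of the selected features (fewer, with a warning, if the block retained
    fewer features).  Column order is deterministic: blocks in cohort
    order, pass-through features in block order, then components by index.
    """
    if not cohort.labelled_mask().all():
        raise ValueError("cohort contains missing labels; run filter_labelled first")
    columns: dict[str, np.ndarray] = {}
    roles: dict[str, tuple[str, str]] = {}
    transforms: dict[str, PcaTransform] = {}
    any_selected = False
    for block in cohort.blocks:
        sel = selection.selected_ids(block.name)
        if not sel:
            logger.warning("assemble_design: block %r has no selected features", block.name)
            continue
        any_selected = True
        if block.kind == "discrete":
            for fid in sel:
                columns[fid] = block.values[fid].to_numpy(dtype=float)
                roles[fid] = ("passthrough", block.name)
        else:
            if L_per_block == 0:
                continue
            l_eff = min(L_per_block, len(sel))
            if l_eff < L_per_block:
                logger.warning(
                    "assemble_design: block %r has only %d selected features; "
                    "retaining %d component(s)", block.name, len(sel), l_eff,
                )
            pca = fit_pca(
                block.values[sel].to_numpy(dtype=float),
                l_eff,
                block=block.name,
                feature_ids=sel,
                scale=scale,
            )
            scores = pca.transform(block.values[sel].to_numpy(dtype=float))
            for j in range(l_eff):
                col = f"{block.name}_PC{j + 1}"
                columns[col] = scores[:, j]
                roles[col] = ("pc", block.name)
            transforms[block.name] = pca
    if not any_selected:
        raise ValueError("no block retained any feature; nothing to assemble")
    X = pd.DataFrame(columns, index=pd.Index(cohort.sample_ids, name="sample_id"))
    return ReducedDataset(
        X, cohort.labels.copy(), roles, transforms, list(cohort.sample_ids)
    )
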