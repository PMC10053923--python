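"""Mid-level fusion of the binned-NMR and LC-MS blocks.

Before concatenation each block is scaled as a unit: every value in the
block is divided by the sum of the block's per-variable standard deviations,

    x_hat = x / sum_sigma(block),

so that the total variation the two analytical platforms contribute to the
fused matrix is balanced regardless of their very different raw intensity
scales and variable counts.  After this block-wise scaling the sum of
per-variable standard deviations within each block equals 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ms import FeatureTable
from .nmr import BinnedNmrMatrix

__all__ = ["BlockScaleResult", "FusedMatrix", "block_scale", "concatenate", "fuse"]

NMR_BLOCK = "NMR"
MS_BLOCK = "MS"


@dataclass
class BlockScaleResult:
    scaled: pd.DataFrame
    sigma_sum: float
    zero_variance: list[str]


@dataclass
class FusedMatrix:
    """Samples x variables matrix carrying block membership and scaling state."""

    values: pd.DataFrame
    block_of: pd.Series  # variable id -> NMR | MS
    scaling_record: dict[str, float]  # block -> sum of variable SDs used

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.values.columns)

    def block(self, name: str) -> pd.DataFrame:
        cols = [v for v in self.values.columns if self.block_of[v] == name]
        return self.values[cols]


def block_scale(X: pd.DataFrame, block_name: str = "block") -> BlockScaleResult:
    """Divide a whole block by the sum of its variable standard deviations.

    Sample standard deviation (ddof=1) is used.  Zero-variance variables
    are retained — they are divided like every other variable — but their
    ids are reported so callers can flag them.
    """
    if X.shape[0] < 2:
        raise ValueError(f"block {block_name!r}: need at least 2 samples to scale")
    if X.isna().any().any():
        raise ValueError(f"block {block_name!r}: NaN values present")
    sd = X.std(ddof=1)
    sigma_sum = float(sd.sum())
    if sigma_sum == 0:
        raise ValueError(f"block {block_name!r} is constant (sum of SDs is zero)")
    return BlockScaleResult(
        scaled=X / sigma_sum,
        sigma_sum=sigma_sum,
        zero_variance=list(sd.index[sd == 0]),
    )


def concatenate(
    nmr_scaled: pd.DataFrame,
    ms_scaled: pd.DataFrame,
    scaling_record: dict[str, float],
) -> FusedMatrix:
    """Column-wise concatenation of two independently block-scaled matrices.

    The two blocks must cover the same sample-id set; the fused row order is
    the NMR block's order.  Variable ids must not collide across blocks.
    """
    nmr_ids = set(nmr_scaled.index)
    ms_ids = set(ms_scaled.index)
    if nmr_ids != ms_ids:
        only_nmr = sorted(nmr_ids - ms_ids)
        only_ms = sorted(ms_ids - nmr_ids)
        raise ValueError(
            f"sample mismatch between blocks: only in NMR {only_nmr}, only in MS {only_ms}"
        )
    clash = set(nmr_scaled.columns) & set(ms_scaled.columns)
    if clash:
        raise ValueError(f"variable ids present in both blocks: {sorted(clash)}")
    ms_aligned = ms_scaled.loc[nmr_scaled.index]
    values = pd.concat([nmr_scaled, ms_aligned], axis=1)
    block_of = pd.Series(
        [NMR_BLOCK] * nmr_scaled.shape[1] + [MS_BLOCK] * ms_scaled.shape[1],
        index=values.columns,
    )
    return FusedMatrix(values=values, block_of=block_of, scaling_record=dict(scaling_record))


def fuse(binned: BinnedNmrMatrix, features: FeatureTable) -> FusedMatrix:
    """Block-scale the binned NMR matrix and the MS area matrix, then fuse."""
    nmr_res = block_scale(binned.values, NMR_BLOCK)
    ms_res = block_scale(features.area_matrix(), MS_BLOCK)
    return concatenate(
        nmr_res.scaled,
        ms_res.scaled,
        {NMR_BLOCK: nmr_res.sigma_sum, MS_BLOCK: ms_res.sigma_sum},
    )


def write_fused(fused: FusedMatrix, path) -> None:
    """Delimited export with a two-row header (variable id, block tag)."""
    header = pd.MultiIndex.from_arrays(
        [fused.values.columns, [fused.block_of[v] for v in fused.values.columns]],
        names=["variable", "block"],
    )
    out = fused.values.copy()
    out.columns = header
    out.to_csv(path)


def read_fused(path) -> FusedMatrix:
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    block_of = pd.Series([b for (_, b) in df.columns], index=[v for (v, _) in df.columns])
    df.columns = block_of.index
    return FusedMatrix(values=df, block_of=block_of, scaling_record={})
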