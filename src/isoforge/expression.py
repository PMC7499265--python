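"""Abundance layers (TPM, FPKM), replicate concordance, representative isoforms.

TPM_i = (c_i / L_i) / sum_j (c_j / L_j) * 1e6 ; FPKM_i = c_i * 1e9 / (L_i * M)
with M the mapped-read total. Effective length is the transcript length
(no fragment-length correction). Replicate concordance is the Pearson r of
log2(TPM + 1) between sample pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def compute_tpm(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("all-zero counts")
    return rate / total * 1e6


def compute_fpkm(
    counts: Sequence[float], lengths: Sequence[float], total_mapped: float
) -> np.ndarray:
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    return counts * 1e9 / (lengths * total_mapped)


@dataclass
class ExpressionMatrix:
    """Transcripts x samples table with raw counts and TPM/FPKM layers."""

    counts: pd.DataFrame  # int counts, index=transcript ids, columns=samples
    lengths: pd.Series  # bp, aligned to counts.index
    tpm: pd.DataFrame
    fpkm: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, lengths: Mapping[str, int] | pd.Series) -> "ExpressionMatrix":
        lengths = pd.Series(lengths).reindex(counts.index)
        if lengths.isna().any():
            missing = lengths[lengths.isna()].index.tolist()[:5]
            raise ValueError(f"missing lengths for transcripts, e.g. {missing}")
        tpm = counts.apply(lambda col: compute_tpm(col.to_numpy(), lengths.to_numpy()))
        fpkm = counts.apply(
            lambda col: compute_fpkm(col.to_numpy(), lengths.to_numpy(), col.sum())
        )
        return cls(counts=counts, lengths=lengths, tpm=tpm, fpkm=fpkm)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def replicate_pcc(tpm: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Sample-pair Pearson correlation matrix on log2(TPM+1) (configurable)."""
    if tpm.shape[1] < 2 or tpm.shape[0] < 3:
        raise ValueError("need >=2 samples and >=3 transcripts")
    data = np.log2(tpm + 1.0) if log_transform else tpm
    mat = pd.DataFrame(
        np.corrcoef(data.to_numpy().T), index=tpm.columns, columns=tpm.columns
    )
    # zero-variance samples yield NaN rows; keep them flagged rather than fail
    return mat


def representative_isoform(
    gene_to_isoforms: Mapping[str, Sequence[str]],
    lengths: Mapping[str, int] | pd.Series,
    mean_tpm: Mapping[str, float] | pd.Series,
    prefer: str = "length",
) -> dict[str, str]:
    """Per gene, the longest isoform; ties broken by higher mean TPM, then id.
    ``prefer="expression"`` swaps the first two keys."""
    lengths = pd.Series(lengths)
    mean_tpm = pd.Series(mean_tpm)
    out = {}
    for gene in sorted(gene_to_isoforms):
        isoforms = list(gene_to_isoforms[gene])
        if not isoforms:
            raise ValueError(f"gene {gene} has no isoforms")
        if prefer == "length":
            key = lambda t: (-lengths[t], -mean_tpm[t], t)
        elif prefer == "expression":
            key = lambda t: (-mean_tpm[t], -lengths[t], t)
        else:
            raise ValueError(f"unknown preference {prefer!r}")
        out[gene] = sorted(isoforms, key=key)[0]
    return out


def tissue_profile(tpm: pd.DataFrame, grouping: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM over replicates per tissue; grouping has sample/tissue columns."""
    if not {"sample", "tissue"} <= set(grouping.columns):
        raise ValueError("grouping needs 'sample' and 'tissue' columns")
    tissue_of = grouping.set_index("sample")["tissue"]
    return tpm.T.groupby(tissue_of).mean().T
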