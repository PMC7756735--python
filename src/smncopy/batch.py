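"""Batch depth normalization for SMN copy-number estimation.

For sample *i* and control gene *k*, the relative coverage is

    Z_ki = (c_i1 + c_i2) / H_ki,

where ``c_i1``/``c_i2`` are the mean depths of SMN1/SMN2 and ``H_ki`` the
mean depth of control gene *k*. The per-sample scale factor

    theta_i = (1/K) * sum_k Z_ki / Zbar_k,    Zbar_k = (1/N) * sum_i Z_ki,

is the sample's combined SMN coverage relative to the batch average; it is
proportional to the total SMN1+SMN2 copy number when the batch averages four
copies. The SMN1 allele fraction at discriminating site *j* is then scaled:

    pi_ij = theta_i * D1_ij / (D1_ij + D2_ij).

By construction the batch mean of theta is exactly 1, and 0 <= pi_ij <=
theta_i. A pi with no covering reads is undefined and is carried as NaN,
never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pileup import SampleCounts
from .registry import SITE_LABELS, LocusRegistry

__all__ = [
    "BatchStatistics",
    "ZeroControlCoverageError",
    "relative_coverage",
    "scale_factors",
    "scaled_proportion",
    "compute_batch",
]


class ZeroControlCoverageError(ValueError):
    """A control gene with zero mean depth: the sample cannot be normalized.

    Such a sample must be excluded or re-sequenced; its coverage is never
    silently imputed.
    """


@dataclass
class BatchStatistics:
    """Normalization results for a batch of N samples over K control genes."""

    sample_ids: list[str]
    z: np.ndarray  # N x K relative coverages
    z_bar: np.ndarray  # K column means
    theta: np.ndarray  # N scale factors
    pi: np.ndarray  # N x 3 scaled proportions (NaN where undefined)

    def row(self, sample_id: str) -> tuple[float, np.ndarray]:
        i = self.sample_ids.index(sample_id)
        return float(self.theta[i]), self.pi[i]


def relative_coverage(counts: SampleCounts, control_order: tuple[str, ...]) -> np.ndarray:
    """Z_i. vector: combined SMN depth over each control-gene depth."""
    smn_total = counts.smn1_mean_depth + counts.smn2_mean_depth
    out = np.empty(len(control_order))
    for k, gene in enumerate(control_order):
        h = counts.control_mean_depth[gene]
        if h <= 0.0:
            raise ZeroControlCoverageError(
                f"sample {counts.sample_id}: control gene {gene} has zero mean "
                "coverage; exclude the sample or re-sequence"
            )
        out[k] = smn_total / h
    return out


def scale_factors(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means Zbar and per-sample scale factors theta from the Z matrix."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 1:
        raise ValueError("z must be an N x K matrix with N >= 1")
    if not np.all(z > 0):
        raise ValueError("all relative coverages must be positive")
    z_bar = z.mean(axis=0)
    theta = (z / z_bar).mean(axis=1)
    return z_bar, theta


def scaled_proportion(theta_i: float, d1: int, d2: int) -> float:
    """pi = theta * D1/(D1+D2); NaN when no reads cover the site."""
    if d1 < 0 or d2 < 0:
        raise ValueError("allele counts must be non-negative")
    if theta_i <= 0:
        raise ValueError("scale factor must be positive")
    if d1 + d2 == 0:
        return math.nan
    return theta_i * d1 / (d1 + d2)


def compute_batch(
    all_counts: list[SampleCounts],
    registry: LocusRegistry,
    skip_on_error: bool = False,
) -> BatchStatistics:
    """Joint normalization of a batch; order-equivariant and deterministic.

    With ``skip_on_error`` a sample failing its preconditions (zero control
    coverage) is dropped from the batch — and hence from Zbar — instead of
    aborting; the caller is expected to report it.
    """
    if not all_counts:
        raise ValueError("empty batch")
    order = registry.control_order
    kept: list[SampleCounts] = []
    rows: list[np.ndarray] = []
    errors: list[ZeroControlCoverageError] = []
    for counts in all_counts:
        try:
            rows.append(relative_coverage(counts, order))
            kept.append(counts)
        except ZeroControlCoverageError as exc:
            if not skip_on_error:
                raise
            errors.append(exc)
    if not kept:
        raise ZeroControlCoverageError("no sample in the batch could be normalized")
    z = np.vstack(rows)
    z_bar, theta = scale_factors(z)
    pi = np.full((len(kept), len(SITE_LABELS)), np.nan)
    for i, counts in enumerate(kept):
        for j, label in enumerate(SITE_LABELS):
            pi[i, j] = scaled_proportion(
                float(theta[i]), counts.d1[label], counts.d2[label]
            )
    stats = BatchStatistics(
        sample_ids=[c.sample_id for c in kept], z=z, z_bar=z_bar, theta=theta, pi=pi
    )
    stats.skipped = errors  # type: ignore[attr-defined]
    return stats
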