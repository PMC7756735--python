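"""Carrier flagging, absolute genotype estimation and silent-carrier detection.

Rules, applied per sample after batch normalization:

* **likely carrier** — scaled SMN1 proportion ``pi`` below 1/3 at *any* of
  the three discriminating positions. The disjunction matters: a single
  SMN1 copy can be missed at one noisy site but rarely at all three.
* **absolute genotype** (SMN1:SMN2 copies) — carriers are matched against
  the expected (scale factor, raw D1/D2 ratio) pairs:
  1:3 -> (1.0, 1/3), 1:2 -> (0.75, 1/2), 1:1 -> (0.5, 1). A genotype is a
  candidate when both coordinates fall within tolerance of its pair; no
  candidate, or the scale factor and the ratios pulling toward different
  genotypes, yields ``inconclusive`` rather than a guess.
* **silent carrier (2+0)** — two SMN1 copies in cis look depth-normal per
  allele fraction but transmit a deleted haplotype. Flagged only when both
  duplication-tag polymorphisms are present *and* the scale factor sits near
  0.75 (2:1) or 0.5 (2:0) *and* every pi sits near 1/2.

Non-carriers still report their scale factor, proportions and variant
screening so a batch review can re-threshold from raw numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .pileup import SampleCounts
from .registry import SITE_LABELS

__all__ = [
    "ClassificationConfig",
    "SampleCall",
    "call_carrier",
    "estimate_genotype",
    "detect_silent_carrier",
    "classify_sample",
    "load_config",
]

CARRIER_GENOTYPES = ("1:1", "1:2", "1:3")


@dataclass(frozen=True)
class ClassificationConfig:
    carrier_pi_threshold: float = 1.0 / 3.0
    theta_centroids: Mapping[str, float] = field(
        default_factory=lambda: {"1:3": 1.0, "1:2": 0.75, "1:1": 0.5}
    )
    ratio_centroids: Mapping[str, float] = field(
        default_factory=lambda: {"1:3": 1.0 / 3.0, "1:2": 0.5, "1:1": 1.0}
    )
    max_theta_distance: float = 0.15
    max_ratio_distance: float = 0.15
    silent_theta_targets: tuple[float, ...] = (0.75, 0.5)
    silent_pi_target: float = 0.5
    silent_theta_tolerance: float = 0.12
    silent_pi_tolerance: float = 0.12
    variant_min_support: int = 3
    variant_min_fraction: float = 0.08

    def __post_init__(self) -> None:
        if self.carrier_pi_threshold <= 0:
            raise ValueError("carrier_pi_threshold must be positive")
        for m in (self.theta_centroids, self.ratio_centroids):
            if sorted(m) != sorted(CARRIER_GENOTYPES):
                raise ValueError("centroids must cover exactly 1:1, 1:2, 1:3")


@dataclass
class SampleCall:
    """Classified result plus every intermediate number, for auditability."""

    sample_id: str
    theta: float
    pi: dict[str, float]
    raw_ratios: dict[str, float]
    likely_carrier: bool
    genotype_estimate: str  # 1:1 | 1:2 | 1:3 | inconclusive | not-carrier
    silent_carrier_flag: bool
    dup_variant_status: dict[str, tuple[int, int, bool]]
    notes: list[str] = field(default_factory=list)


def call_carrier(pi: Mapping[str, float], config: ClassificationConfig) -> bool:
    """True iff pi falls below the carrier threshold at ANY position."""
    return any(pi[label] < config.carrier_pi_threshold for label in SITE_LABELS)


def estimate_genotype(
    theta: float,
    raw_ratios: Mapping[str, float],
    config: ClassificationConfig,
) -> str:
    """Match (theta, median D1/D2 ratio) against the carrier-genotype centroids.

    The median of the three per-site ratios is used so one noisy site cannot
    dominate. Candidates must match on both coordinates; among several the
    closest (Euclidean) wins; none means inconclusive.
    """
    ratios = [raw_ratios[label] for label in SITE_LABELS]
    ratios = [r for r in ratios if not math.isnan(r)]
    if not ratios:
        return "inconclusive"
    med = float(np.median(ratios))
    candidates: list[tuple[float, str]] = []
    for genotype in CARRIER_GENOTYPES:
        dt = abs(theta - config.theta_centroids[genotype])
        dr = abs(med - config.ratio_centroids[genotype])
        if dt <= config.max_theta_distance and dr <= config.max_ratio_distance:
            candidates.append((math.hypot(dt, dr), genotype))
    if not candidates:
        return "inconclusive"
    return min(candidates)[1]


def _variant_present(
    support: tuple[int, int], config: ClassificationConfig
) -> tuple[bool, bool]:
    """(present, assessable) for one duplication-tag variant."""
    sup, cov = support
    if cov == 0:
        return False, False
    present = sup >= config.variant_min_support and sup / cov >= config.variant_min_fraction
    return present, True


def detect_silent_carrier(
    counts: SampleCounts,
    theta: float,
    pi: Mapping[str, float],
    config: ClassificationConfig,
) -> tuple[bool, list[str]]:
    """Silent-carrier (2+0 / 2+1) rule: both tag variants, theta near a
    duplication target, every pi near 1/2."""
    notes: list[str] = []
    present: list[bool] = []
    for label, support in counts.dup_variant_support.items():
        ok, assessable = _variant_present(support, config)
        if not assessable:
            notes.append(f"{label}: unassessable (no covering reads)")
        present.append(ok)
    if not all(present):
        return False, notes
    notes.append("both duplication-tag variants present")
    theta_ok = any(
        abs(theta - t) <= config.silent_theta_tolerance
        for t in config.silent_theta_targets
    )
    if not theta_ok:
        notes.append("theta inconsistent with 2+0/2+1")
        return False, notes
    pis = [pi[label] for label in SITE_LABELS]
    if any(math.isnan(p) for p in pis):
        notes.append("undefined pi: silent-carrier rule not evaluable")
        return False, notes
    pi_ok = all(
        abs(p - config.silent_pi_target) <= config.silent_pi_tolerance for p in pis
    )
    if not pi_ok:
        notes.append("pi inconsistent with duplication haplotype (expected ~1/2)")
        return False, notes
    notes.append(
        "theta and pi consistent with an SMN1 duplication haplotype (2+0 or 2+1)"
    )
    return True, notes


def classify_sample(
    counts: SampleCounts,
    theta: float,
    pi_values,
    config: ClassificationConfig = ClassificationConfig(),
) -> SampleCall:
    """Compose the three rules into one auditable per-sample call."""
    pi = {label: float(p) for label, p in zip(SITE_LABELS, pi_values)}
    raw_ratios = {
        label: (counts.d1[label] / counts.d2[label] if counts.d2[label] > 0 else math.nan)
        for label in SITE_LABELS
    }
    notes: list[str] = []
    dup_status = {
        label: (*support, _variant_present(support, config)[0])
        for label, support in counts.dup_variant_support.items()
    }

    if any(math.isnan(p) for p in pi.values()):
        notes.append("undefined scaled proportion (no covering reads): inconclusive")
        return SampleCall(
            sample_id=counts.sample_id,
            theta=theta,
            pi=pi,
            raw_ratios=raw_ratios,
            likely_carrier=False,
            genotype_estimate="inconclusive",
            silent_carrier_flag=False,
            dup_variant_status=dup_status,
            notes=notes,
        )

    likely = call_carrier(pi, config)
    genotype = (
        estimate_genotype(theta, raw_ratios, config) if likely else "not-carrier"
    )
    silent, silent_notes = detect_silent_carrier(counts, theta, pi, config)
    notes.extend(silent_notes)
    if all(p < 0.05 for p in pi.values()):
        notes.append(
            "all scaled proportions near zero: consistent with absence of SMN1 "
            "(affected genotype); confirm by an orthogonal assay"
        )
    return SampleCall(
        sample_id=counts.sample_id,
        theta=theta,
        pi=pi,
        raw_ratios=raw_ratios,
        likely_carrier=likely,
        genotype_estimate=genotype,
        silent_carrier_flag=silent,
        dup_variant_status=dup_status,
        notes=notes,
    )


_FLOAT_FIELDS = {
    "carrier_pi_threshold",
    "max_theta_distance",
    "max_ratio_distance",
    "silent_pi_target",
    "silent_theta_tolerance",
    "silent_pi_tolerance",
    "variant_min_fraction",
}


def load_config(path: str) -> ClassificationConfig:
    """Read overrides from a plain ``key = value`` file; defaults embedded."""
    overrides: dict[str, object] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in _FLOAT_FIELDS:
                overrides[key] = float(value)
            elif key == "variant_min_support":
                overrides[key] = int(value)
            elif key == "silent_theta_targets":
                overrides[key] = tuple(float(v) for v in value.split(","))
            else:
                raise ValueError(f"unknown configuration key {key!r}")
    return replace(ClassificationConfig(), **overrides)
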