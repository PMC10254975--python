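"""Probe- and sample-level quality-control filters for methylation matrices.

Filters operate on beta-value / detection-p matrices plus probe
annotation, not on raw array intensities.  Probes are removed for
failing detection in too many samples, for lying on a sex chromosome,
or for membership in a cross-reactive or SNP-overlap blacklist; samples
are removed when their aggregate detection p-value is too high.
Reasons are assigned in a fixed first-matching-rule order so the
exclusion report is deterministic and its counts sum to the number of
removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QCConfig", "compute_beta", "filter_probes", "filter_samples"]

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}

# reasons in application order; first matching rule wins
PROBE_REASONS = ("detection", "sex_chromosome", "cross_reactive", "snp")


@dataclass
class QCConfig:
    """Thresholds and blacklists for probe/sample filtering.

    ``probe_fail_sample_fraction`` is the fraction of samples in which a
    probe may exceed the detection threshold before removal.  The sample
    rule aggregates detection p per sample by ``mean`` (default) or
    ``sum``.
    """

    detection_p_threshold: float = 0.01
    probe_fail_sample_fraction: float = 0.01
    sample_detection_rule: str = "mean"
    sample_detection_threshold: float = 0.01
    cross_reactive: frozenset = field(default_factory=frozenset)
    snp_probes: frozenset = field(default_factory=frozenset)
    autosomes_only: bool = True

    def __post_init__(self):
        if not 0 < self.detection_p_threshold < 1:
            raise ValueError("detection_p_threshold must be in (0,1)")
        if not 0 <= self.probe_fail_sample_fraction <= 1:
            raise ValueError("probe_fail_sample_fraction must be in [0,1]")
        if self.sample_detection_rule not in ("mean", "sum"):
            raise ValueError("sample_detection_rule must be 'mean' or 'sum'")
        self.cross_reactive = frozenset(self.cross_reactive)
        self.snp_probes = frozenset(self.snp_probes)


def compute_beta(meth, unmeth, offset=0.0):
    """Beta value: methylated intensity over total probe intensity,
    ``meth / (meth + unmeth + offset)``, in [0, 1].

    Accepts scalars or arrays; raises when any denominator is zero.
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0) or np.any(np.asarray(offset) < 0):
        raise ValueError("intensities and offset must be non-negative")
    denom = meth + unmeth + offset
    if np.any(denom <= 0):
        raise ValueError("beta undefined: methylated + unmethylated + offset is 0")
    beta = meth / denom
    return float(beta) if beta.ndim == 0 else beta


def _check_alignment(beta: pd.DataFrame, detection_p: pd.DataFrame) -> None:
    if list(beta.index) != list(detection_p.index) or list(beta.columns) != list(
        detection_p.columns
    ):
        raise ValueError("detection-p matrix is not aligned with the beta matrix")


def filter_probes(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    annotation,
    config: QCConfig,
) -> tuple[list, pd.DataFrame]:
    """Probe filter: returns (retained probe ids, exclusion report).

    A probe is removed if its detection p exceeds the threshold in more
    than ``probe_fail_sample_fraction`` of samples, if it lies on a sex
    chromosome (with ``autosomes_only``), or if it appears in the
    cross-reactive or SNP blacklist.  The report has one row per removed
    probe with the first matching reason.
    """
    _check_alignment(beta, detection_p)
    chrom = getattr(annotation, "probes", annotation)
    fail_frac = (detection_p.to_numpy() > config.detection_p_threshold).mean(axis=1)
    reasons: dict[str, str] = {}
    for probe, frac in zip(beta.index, fail_frac):
        if frac > config.probe_fail_sample_fraction:
            reasons[probe] = "detection"
        elif (
            config.autosomes_only
            and probe in chrom.index
            and str(chrom.loc[probe, "chrom"]) in SEX_CHROMOSOMES
        ):
            reasons[probe] = "sex_chromosome"
        elif probe in config.cross_reactive:
            reasons[probe] = "cross_reactive"
        elif probe in config.snp_probes:
            reasons[probe] = "snp"
    retained = [p for p in beta.index if p not in reasons]
    report = pd.DataFrame(
        {"id": list(reasons), "reason": list(reasons.values())}
    )
    return retained, report


def filter_samples(
    detection_p: pd.DataFrame, config: QCConfig
) -> tuple[list, pd.DataFrame]:
    """Sample filter: retains samples whose aggregate detection p-value
    (mean by default, sum if configured) is below the threshold."""
    if detection_p.size == 0:
        raise ValueError("empty detection-p matrix")
    agg = (
        detection_p.mean(axis=0)
        if config.sample_detection_rule == "mean"
        else detection_p.sum(axis=0)
    )
    bad = agg[agg >= config.sample_detection_threshold]
    retained = [s for s in detection_p.columns if s not in set(bad.index)]
    report = pd.DataFrame({"id": bad.index, "reason": "detection"})
    return retained, report
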