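"""Exon-level copy-number calls from SNP-array Log R Ratios.

The mean LRR of a sample's exonic probes in a region is compared against
the distribution of control-sample means: a strongly depressed z-score
indicates a heterozygous deletion (copy number 1) and a mean below an
absolute floor indicates a homozygous deletion (copy number 0). Defaults
follow standard Illumina LRR expectations (~-0.45 for CN1, <= -1.5 for
CN0); all thresholds are configurable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["LrrObservation", "CnvThresholds", "CnvCall", "call_cnv"]


@dataclass(frozen=True)
class LrrObservation:
    sample_id: str
    probe_id: str
    region: str  # e.g. "exon7", "exon14"
    lrr: float


@dataclass(frozen=True)
class CnvThresholds:
    z_del: float = -3.0     # z-score below which a deletion is called
    hom_floor: float = -1.5  # mean LRR at or below which CN0 is called


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    region: str
    mean_lrr: float
    z: float
    copy_number: int
    confidence_note: str = ""


def call_cnv(
    sample_obs: Sequence[LrrObservation],
    controls: Sequence[LrrObservation],
    region: str,
    thresholds: CnvThresholds = CnvThresholds(),
) -> CnvCall:
    """Call the copy number of one region for one sample.

    ``z = (mean_sample - mean_of_control_means) / sd_of_control_means``
    where each control sample contributes its own mean over the region's
    probes. Copy number 2 when ``z > z_del``; otherwise 1 when the sample
    mean is above ``hom_floor`` and 0 when at or below it. Requires >= 1
    sample probe and >= 2 control samples; identical control means are a
    hard error (degenerate controls).
    """
    s_vals = [o.lrr for o in sample_obs if o.region == region]
    if not s_vals:
        raise ValueError(f"no sample probes for region {region}")
    sample_ids = {o.sample_id for o in sample_obs if o.region == region}
    if len(sample_ids) != 1:
        raise ValueError("sample observations must come from one sample")

    ctrl_means: dict[str, list[float]] = {}
    for o in controls:
        if o.region == region:
            ctrl_means.setdefault(o.sample_id, []).append(o.lrr)
    if len(ctrl_means) < 2:
        raise ValueError("need >= 2 control samples for the region")
    means = np.array([np.mean(v) for v in ctrl_means.values()])
    sd = means.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate controls: zero variance across control means")

    mean_lrr = float(np.mean(s_vals))
    z = float((mean_lrr - means.mean()) / sd)
    if z > thresholds.z_del:
        cn, note = 2, "within control distribution"
    elif mean_lrr > thresholds.hom_floor:
        cn, note = 1, f"z={z:.2f} <= z_del={thresholds.z_del}"
    else:
        cn, note = 0, f"mean LRR {mean_lrr:.2f} <= hom_floor={thresholds.hom_floor}"
    return CnvCall(sample_ids.pop(), region, mean_lrr, z, cn, note)
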