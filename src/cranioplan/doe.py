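"""Design of experiments over surgical configurations.

Each synthetic patient receives roughly eighty distinct surgical
configurations (count drawn as round(Normal(80, 2.5)) clipped to
[75, 85]).  Osteotomy ratios follow truncated normals centred mid-range
with SD = range/4 (so about 95% of the untruncated mass lies in-bounds),
and each spring site draws uniformly from the three-model catalogue.  A
Latin-hypercube option gives space-filling coverage of the ratio box
instead of the normal draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from cranioplan.anatomy import PatientParams
from cranioplan.springs import (
    A_RANGE,
    AP_RANGE,
    LAT_RANGE,
    SPRING_CATALOGUE,
    SpringSpec,
    SurgicalConfig,
)

__all__ = ["DoEPlan", "generate_doe"]

COUNT_MEAN = 80.0
COUNT_SD = 2.5
COUNT_BOUNDS = (75, 85)


@dataclass
class DoEPlan:
    patient_id: int
    configs: list[SurgicalConfig]
    seed: int

    def __len__(self) -> int:
        return len(self.configs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cid, c in enumerate(self.configs):
            rows.append({
                "patient_id": self.patient_id,
                "config_id": cid,
                "A": c.A, "AP": c.AP, "LAT": c.LAT,
                "ant_model": c.anterior_spring.model_name,
                "ant_k": c.anterior_spring.stiffness,
                "ant_L0": c.anterior_spring.free_length,
                "post_model": c.posterior_spring.model_name,
                "post_k": c.posterior_spring.stiffness,
                "post_L0": c.posterior_spring.free_length,
                "seed": self.seed,
            })
        return pd.DataFrame(rows)


def _truncated_normal(rng, lo, hi, size):
    mean, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def generate_doe(patient: PatientParams, seed: int,
                 catalogue: tuple[SpringSpec, ...] = SPRING_CATALOGUE,
                 patient_id: int = 0, latin_hypercube: bool = False) -> DoEPlan:
    """Sample a per-patient set of surgical configurations, deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    count = int(np.clip(np.rint(rng.normal(COUNT_MEAN, COUNT_SD)), *COUNT_BOUNDS))

    if latin_hypercube:
        sampler = qmc.LatinHypercube(d=3, seed=rng)
        unit = sampler.random(count)
        lo = np.array([A_RANGE[0], AP_RANGE[0], LAT_RANGE[0]])
        hi = np.array([A_RANGE[1], AP_RANGE[1], LAT_RANGE[1]])
        ratios = qmc.scale(unit, lo, hi)
        a, ap, lat = ratios[:, 0], ratios[:, 1], ratios[:, 2]
    else:
        a = _truncated_normal(rng, *A_RANGE, size=count)
        ap = _truncated_normal(rng, *AP_RANGE, size=count)
        lat = _truncated_normal(rng, *LAT_RANGE, size=count)

    # redraw any config violating AP > A (cannot occur with the default
    # disjoint ranges, but the bounds are configurable)
    bad = np.flatnonzero(ap <= a)
    while bad.size:
        a[bad] = _truncated_normal(rng, *A_RANGE, size=bad.size)
        ap[bad] = _truncated_normal(rng, *AP_RANGE, size=bad.size)
        bad = np.flatnonzero(ap <= a)

    ant = rng.integers(0, len(catalogue), size=count)
    post = rng.integers(0, len(catalogue), size=count)

    configs = [
        SurgicalConfig(A=float(a[i]), AP=float(ap[i]), LAT=float(lat[i]),
                       anterior_spring=catalogue[ant[i]],
                       posterior_spring=catalogue[post[i]])
        for i in range(count)
    ]
    return DoEPlan(patient_id=patient_id, configs=configs, seed=seed)
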