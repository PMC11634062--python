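from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pasnv.scoring import SurrogateScorer, WINDOW_FLANK


def window_with(hexamer: str, start_offset: int, fill: str = "C",
                flank: int = WINDOW_FLANK) -> str:
    """A fill-base window with one hexamer starting at the given offset."""
    length = 2 * flank + 1
    idx = start_offset + flank
    assert 0 <= idx <= length - len(hexamer)
    return fill * idx + hexamer + fill * (length - idx - len(hexamer))


@pytest.fixture(scope="session")
def surrogate() -> SurrogateScorer:
    return SurrogateScorer()


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated study shared by read-only tests."""
    from pasnv import simulate as sim
    from pasnv.classify import build_records

    cfg = sim.SimConfig(seed=11, n_genes=40, n_tumours=60,
                        sel_strength=0.5, tsg_boost=3.0)
    scorer = SurrogateScorer()
    genome, sites, roles = sim.make_genome(cfg)
    normal = sim.make_normal_cohort(cfg, genome, sites, scorer)
    cancer = sim.make_cancer_cohort(cfg, genome, sites, roles, scorer)
    variants = pd.concat([normal, cancer], ignore_index=True)
    records, qc = build_records(variants, sites, genome, scorer)
    return {
        "config": cfg, "genome": genome, "sites": sites, "roles": roles,
        "normal": normal, "cancer": cancer, "records": records, "qc": qc,
    }
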