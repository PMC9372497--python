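from __future__ import annotations

import numpy as np
import pytest

from netfuse import (
    NetworkInstance,
    PlantedDesign,
    ROI,
    combine,
    generate_stack,
)
from netfuse.synthetic_data import REDUCED_LAYOUT


def make_instance(
    atlas: str,
    lobe_counts: dict[str, int],
    network: str = "FPN",
    z: float = 0.0,
) -> NetworkInstance:
    """Build a synthetic instance with the given per-lobe ROI counts."""
    rois = []
    k = 0
    for lobe, count in lobe_counts.items():
        for _ in range(count):
            rois.append(
                ROI(
                    roi_id=f"r{k + 1:03d}",
                    name=f"{atlas} region {k + 1}",
                    mni=(-60.0 + 4.0 * k, 30.0, z),
                    lobe=lobe,
                    source_atlas=atlas,
                    source_network=network,
                )
            )
            k += 1
    return NetworkInstance(network_concept=network, instance_name=atlas,
                           rois=rois)


@pytest.fixture(scope="session")
def table1_instances() -> list[NetworkInstance]:
    """Four size-faithful instances: 10/21/24/17 ROIs with the published
    frontal/parietal split 6+4, 13+8, 17+7, 11+6."""
    return [
        make_instance("aal-syn", {"frontal": 6, "parietal": 4}, z=0),
        make_instance("dosenbach160-syn", {"frontal": 13, "parietal": 8},
                      z=6),
        make_instance("power264-syn", {"frontal": 17, "parietal": 7}, z=12),
        make_instance("willard499-syn", {"frontal": 11, "parietal": 6},
                      z=18),
    ]


@pytest.fixture(scope="session")
def unclipped_instances() -> dict[str, NetworkInstance]:
    """Pre-clipping instances with out-of-boundary lobes: a 25-ROI FPN with
    one temporal ROI, a 24-region ECN with temporal/limbic/cerebellar
    regions, and a 9-ROI FPN with two insula ROIs."""
    return {
        "power264-syn": make_instance(
            "power264-syn", {"frontal": 17, "parietal": 7, "temporal": 1}
        ),
        "willard499-syn": make_instance(
            "willard499-syn",
            {"frontal": 11, "parietal": 6, "temporal": 1, "limbic": 1,
             "cerebellum": 5},
        ),
        "gao32-syn": make_instance(
            "gao32-syn", {"frontal": 4, "parietal": 3, "insula": 2}
        ),
    }


@pytest.fixture(scope="session")
def reduced_design() -> PlantedDesign:
    return PlantedDesign(layout=REDUCED_LAYOUT, n_subjects=8, t=60, seed=123)


@pytest.fixture(scope="session")
def reduced_pipeline(reduced_design):
    """(design, instances, ccn, stack) at the fast test scale."""
    instances, ccn, stack = generate_stack(reduced_design)
    return reduced_design, instances, ccn, stack


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
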