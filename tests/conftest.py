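"""Shared fixtures: small synthetic configurations sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from restnh.io import BoldSeries, NetworkMask, SubjectRecord
from restnh.synth import NhEffect, RegionSpec, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Tiny two-region cohort: fast enough for per-test regeneration."""
    return SyntheticConfig(
        n_patients=4,
        n_controls=4,
        grid_shape=(12, 12, 8),
        n_volumes=96,
        region_specs=(
            RegionSpec("region_a", (3, 3, 4), 2.0),
            RegionSpec("region_b", (8, 8, 4), 2.0),
        ),
        falff_effect_region="region_a",
        nh_effects=(NhEffect("region_b", 0.5, 0.3),),
        clinical_link_region="region_b",
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_subject(small_cohort):
    """One patient's generated raw data from the small cohort."""
    record = small_cohort.records[0]
    return record, small_cohort.subject_data(record.subject_id)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251002)


@pytest.fixture()
def flat_mask() -> NetworkMask:
    """A 5x5x3 all-inside single-region mask with 2 mm voxels."""
    labels = np.ones((5, 5, 3), dtype=np.int32)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return NetworkMask(label_data=labels, affine=affine, region_names={1: "all"})


def make_bold(data: np.ndarray, tr: float = 2.0, voxel_mm: float = 2.0) -> BoldSeries:
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return BoldSeries(voxel_data=data, affine=affine, tr_seconds=tr, subject_id="test")


def make_records(n_patients: int, n_controls: int, seed: int = 0) -> list[SubjectRecord]:
    """Minimal subject records with covariates filled (incl. mean FD)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_patients + n_controls):
        group = "patient" if i < n_patients else "control"
        records.append(
            SubjectRecord(
                subject_id=f"s{i:03d}",
                group=group,
                age_years=float(30 + rng.normal(0, 5)),
                sex="male" if rng.random() < 0.5 else "female",
                education_years=float(12 + rng.normal(0, 2)),
                ybocs_total=float(abs(rng.normal(20, 5))) if group == "patient" else 1.0,
                mean_fd_mm=float(0.04 + 0.01 * rng.random()),
            )
        )
    return records
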