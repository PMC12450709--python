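import numpy as np
import pytest
from hypothesis import settings

from petsynth.phantom import PhantomSpec, generate_phantom

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from petsynth.volumes import Cohort, Genotype, Group, Modality, PairedScan, Volume


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Small, quiet phantom for fast unit tests."""
    return PhantomSpec(shape=(16, 16, 16), n_blobs=1, seed=7)


@pytest.fixture(scope="session")
def tiny_scan(tiny_spec) -> "PairedScan":
    return generate_phantom(tiny_spec, "sub-001", 1, Group.HC, Genotype.HAB)


def make_micro_scan(
    subject_id: str,
    session: int = 1,
    group=Group.HC,
    genotype=Genotype.HAB,
    shape=(4, 4, 4),
    seed: int = 0,
) -> PairedScan:
    """Minimal in-memory scan for split/metadata logic tests (no phantom cost)."""
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=np.uint8)
    return PairedScan(
        subject_id=subject_id,
        session=session,
        group=group,
        genotype=genotype,
        mri=Volume(rng.random(shape), modality=Modality.MRI),
        pet=Volume(rng.random(shape), modality=Modality.PET),
        mask=Volume(mask, modality=Modality.MASK),
    )


def make_micro_cohort(subject_sessions: dict[str, int], groups=None, genotypes=None) -> Cohort:
    """Cohort of micro scans: subject -> number of sessions."""
    groups = groups or {}
    genotypes = genotypes or {}
    scans = []
    for i, (sid, n_sessions) in enumerate(subject_sessions.items()):
        for sess in range(1, n_sessions + 1):
            scans.append(
                make_micro_scan(
                    sid,
                    sess,
                    group=groups.get(sid, Group.HC),
                    genotype=genotypes.get(sid, Genotype.HAB),
                    seed=i * 100 + sess,
                )
            )
    return Cohort(scans)
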