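"""Shared fixtures: small manifests and seeded synthetic tables."""

import pytest

import luxscreen as lx

#: seed used by every fixed-seed test in the suite.
SEED = 0


@pytest.fixture(scope="session")
def full_manifest() -> lx.StrainManifest:
    """The packaged 137-gene RP library with its 9 non-viable strains."""
    return lx.build_strain_manifest(19, 59, lx.NONVIABLE_GENES)


@pytest.fixture(scope="session")
def small_manifest() -> lx.StrainManifest:
    """A 8-gene synthetic library (2 singles + 3 pairs) for cheap tests."""
    return lx.build_strain_manifest(2, 3, [])


@pytest.fixture(scope="session")
def screen_table(full_manifest) -> lx.ReadoutTable:
    """One seeded full screen with the planted selective strain."""
    return lx.simulate_screen(
        full_manifest,
        [lx.EffectSpec("RPL40A", 2.7, 1.0)],
        lx.SimConfig.screen(seed=SEED),
    )


def paper_panel_specs() -> list[lx.EffectSpec]:
    """The 29-compound panel composition: one selective boost (1.7x FF at
    top dose, REN flat), two non-selective actives (2x on both reporters),
    twenty-six nulls."""
    specs = []
    for i in range(29):
        cid = f"C{i + 1:02d}"
        if cid == "C17":
            specs.append(lx.EffectSpec(cid, 1.7, 1.0))
        elif cid in ("C07", "C25"):
            specs.append(lx.EffectSpec(cid, 2.0, 2.0))
        else:
            specs.append(lx.EffectSpec(cid))
    return specs


@pytest.fixture(scope="session")
def panel_table() -> lx.ReadoutTable:
    return lx.simulate_dose_panel(paper_panel_specs(), lx.SimConfig.dual_glo(seed=SEED))
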