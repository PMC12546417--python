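import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def anchovy_like_record():
    """A marine record carrying everything the most specific tier needs."""
    from nppu import SpeciesRecord, TrophicParameters

    return SpeciesRecord(
        species="Engraulis synthetica",
        common_name="synthetic anchovy",
        trophic=TrophicParameters(TL=3.2, TL_SD=0.25, TE=0.119, ecosystem="Upwelling"),
        C_specific=105.0,
    )


@pytest.fixture
def coproduct_spec():
    from nppu import CoproductSpec

    return CoproductSpec(
        yield_meal=0.2, yield_oil=0.05, energy_meal=18.5, energy_oil=39.0,
        yield_source="specific",
    )
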