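import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from clustershift.types import (  # noqa: E402
    HybridisationSite,
    MarkerRecord,
    SimConfig,
    TrueDeletion,
)


@pytest.fixture
def three_site_marker():
    """The canonical 3-site probe: allele A on 6A, allele B on 6B/6D.

    Euploid signal (2, 4): theta = (2/pi) atan(2) = 0.70483, R = 6.
    With the 6A site deleted: theta = 1.0, R = 4; heterozygous: theta =
    (2/pi) atan(4) = 0.84404, R = 5.
    """
    return MarkerRecord(
        snp_index=1,
        name="m3",
        chromosome="6A",
        span_start=32_658_889,
        span_end=32_658_989,
        sites=(
            HybridisationSite("6A", 32_658_889, "A"),
            HybridisationSite("6B", 32_658_000, "B"),
            HybridisationSite("6D", 32_659_500, "B"),
        ),
    )


@pytest.fixture
def small_deletion_config():
    """A 20 Mb homozygous 6A deletion on a 60-marker panel, noise-free."""
    return SimConfig(
        n_markers=60,
        seed=11,
        n_panel=6,
        noise_sd=0.0,
        deletions={"mut": [TrueDeletion("6A", 20_000_000, 40_000_000)]},
    )


@pytest.fixture
def noisy_deletion_config():
    """Same design under the default channel noise, with a 96-line panel."""
    return SimConfig(
        n_markers=150,
        seed=23,
        n_panel=24,
        noise_sd=0.05,
        deletions={"mut": [TrueDeletion("6A", 30_000_000, 55_000_000)]},
    )
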