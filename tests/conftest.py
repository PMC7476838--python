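import pytest

from rbliquid.variants import AlleleCount, DetectionThresholds, VariantKey

SNV = VariantKey("chr13", 48941648, "C", "T")


def make_count(
    alt: int,
    depth: int,
    sample_id: str = "P99-cfdna",
    role: str = "cfdna",
    artifact: int = 0,
    fwd: int | None = None,
    variant: VariantKey = SNV,
) -> AlleleCount:
    """AlleleCount builder with a balanced default strand split."""
    if fwd is None:
        fwd = alt // 2
    return AlleleCount(
        variant=variant,
        sample_id=sample_id,
        role=role,
        depth=depth,
        alt_reads=alt,
        alt_artifact_reads=artifact,
        alt_fwd=fwd,
        alt_rev=alt - fwd,
    )


@pytest.fixture
def snv() -> VariantKey:
    return SNV


@pytest.fixture
def thresholds() -> DetectionThresholds:
    return DetectionThresholds()
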