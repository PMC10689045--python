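"""Shared synthetic fixtures: one small ground-truth experiment reused widely."""

import pytest
from hypothesis import HealthCheck, settings

from atacprep.simulate import (
    emit_bam,
    emit_reads,
    make_reference,
    plant_peaks,
    simulate_experiment,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference():
    return make_reference({"chr1": 200_000, "chr2": 120_000, "chrM": 16_000}, seed=11)


@pytest.fixture(scope="session")
def peaks(reference):
    return plant_peaks(reference, 30, (300, 500), seed=12)


@pytest.fixture(scope="session")
def truth(reference, peaks):
    """~85 barcodes, ~2-3k read pairs, 15% PCR duplication."""
    return simulate_experiment(
        reference,
        peaks,
        n_cells=25,
        n_ambient=60,
        frags_per_cell_range=(60, 120),
        frags_per_ambient_range=(1, 20),
        frip_cell=0.7,
        frip_ambient=0.05,
        dup_rate=0.15,
        barcode_len=12,
        seed=13,
    )


@pytest.fixture(scope="session")
def emission(truth, tmp_path_factory):
    """Index-FASTQ reads with 20% planted single-base barcode errors."""
    out = tmp_path_factory.mktemp("reads")
    return emit_reads(truth, out, mode="index-fastq", barcode_error_rate=0.2, seed=14)


@pytest.fixture(scope="session")
def tagged_bam(truth, tmp_path_factory):
    """Coordinate-sorted BAM with barcode-prefixed read names (untagged)."""
    out = tmp_path_factory.mktemp("bam")
    return emit_bam(truth, str(out / "aligned.bam"), seed=15)


@pytest.fixture(scope="session")
def chrom_sizes_file(reference, tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "chrom.sizes"
    reference.write_chrom_sizes(path)
    return str(path)
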