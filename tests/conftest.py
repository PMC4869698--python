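import numpy as np
import pytest

from domdev.grouped import GenotypeClassSummary
from domdev.synthetic import VariantRecord


@pytest.fixture
def fto_class_summary() -> GenotypeClassSummary:
    """Published genotype-class BMI summary used across modules."""
    return GenotypeClassSummary(
        n=[42835, 57524, 19329],
        mean=[27.27, 27.54, 28.07],
        sd=[4.68, 4.80, 5.11],
    )


def make_hardcall_variant(
    counts: tuple[int, int, int],
    info: float = 1.0,
    vid: str = "v1",
    pos: int = 1000,
    chrom: str = "1",
    shuffle_seed: int | None = None,
) -> VariantRecord:
    """Variant with one-hot genotype probabilities realising exact class counts."""
    calls = np.repeat([0, 1, 2], counts)
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(calls)
    probs = np.zeros((calls.size, 3))
    probs[np.arange(calls.size), calls] = 1.0
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        vid=vid,
        ref_allele="A",
        alt_allele="G",
        info=info,
        genotype_probs=probs,
    )


def make_dosage_variant(
    dosages: np.ndarray, info: float = 1.0, vid: str = "v1", pos: int = 1000
) -> VariantRecord:
    """Variant whose probabilities realise the given dosages exactly."""
    d = np.asarray(dosages, dtype=float)
    probs = np.zeros((d.size, 3))
    low = d <= 1.0
    probs[low, 1] = d[low]
    probs[low, 0] = 1.0 - d[low]
    probs[~low, 1] = 2.0 - d[~low]
    probs[~low, 2] = d[~low] - 1.0
    return VariantRecord(
        chrom="1", pos=pos, vid=vid, ref_allele="A", alt_allele="G",
        info=info, genotype_probs=probs,
    )
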