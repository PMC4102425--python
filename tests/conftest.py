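import numpy as np
import pytest

from nhejscar import (
    CallParams,
    CutReference,
    CutSite,
    DetectionWindow,
    ReporterConstruct,
    derive_cut_reference,
    detection_window,
    make_construct,
)


@pytest.fixture(scope="session")
def toy_cutref() -> CutReference:
    """The worked microhomology example: flanks ACGTCAT / CATGGA share CAT."""
    return CutReference(left_flank="ACGTCAT", right_flank="CATGGA", cut_coordinate=7)


@pytest.fixture(scope="session")
def small_assay():
    """A small random construct with a planted 7-bp repeat and known window."""
    construct, cutref = make_construct(
        seed=11,
        intron_len_5p=200,
        intron_len_3p=180,
        primer_offset_5p=150,
        primer_offset_3p=120,
        planted_repeats=[(7, 40, 30)],
    )
    window = detection_window(construct, cutref)
    return construct, cutref, window


@pytest.fixture(scope="session")
def repeat_assay():
    """A tiny construct whose only long microhomology is a planted 7-bp repeat.

    The window is small enough that chance microhomology stays below 5 bp, so
    the planted repeat is provably the longest and the only MMEJ joint.
    """
    construct, cutref = make_construct(
        seed=5,
        intron_len_5p=45,
        intron_len_3p=40,
        primer_offset_5p=30,
        primer_offset_3p=25,
        primer_len=12,
        planted_repeats=[(7, 12, 9)],
        max_background_mh=4,
    )
    window = detection_window(construct, cutref)
    return construct, cutref, window


@pytest.fixture(scope="session")
def default_params(small_assay) -> CallParams:
    _, _, window = small_assay
    return CallParams(window=window)


def random_flanks(rng: np.random.Generator, len_left: int, len_right: int):
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, len_left))
    right = "".join(rng.choice(bases, len_right))
    return CutReference(left_flank=left, right_flank=right, cut_coordinate=len_left)
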