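import numpy as np
import pytest

from dicerscan import synthetic_data as sd


@pytest.fixture(scope="session")
def design() -> sd.LibraryDesign:
    return sd.LibraryDesign()


@pytest.fixture(scope="session")
def library(design):
    return sd.build_variant_library(design)


@pytest.fixture(scope="session")
def unique_library(library):
    unique, index = sd.dedup_reference(library)
    return unique, index


def random_hairpin(rng: np.random.Generator, max_stem: int = 12) -> str:
    """Random single-hairpin dot-bracket: stacked pairs interleaved with
    bulges, symmetric and asymmetric internal loops, plus a 3' tail."""
    n_pairs = int(rng.integers(2, max_stem))
    left, right = [], []
    for _ in range(n_pairs - 1):
        left.append("(")
        right.append(")")
        kind = rng.integers(0, 5)
        if kind == 1:  # symmetric internal loop
            k = int(rng.integers(1, 4))
            left.extend("." * k)
            right.extend("." * k)
        elif kind == 2:  # asymmetric internal loop
            k5, k3 = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            while k3 == k5:
                k3 = int(rng.integers(1, 4))
            left.extend("." * k5)
            right.extend("." * k3)
        elif kind == 3:  # bulge, one side only
            k = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                left.extend("." * k)
            else:
                right.extend("." * k)
    left.append("(")
    right.append(")")
    loop = "." * int(rng.integers(3, 9))
    tail = "." * int(rng.integers(0, 4))
    return "".join(left) + loop + "".join(reversed(right)) + tail
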