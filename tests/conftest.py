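import numpy as np
import pytest

from dermcascade.synthetic import (LesionRecord, SyntheticCohortSpec,
                                   SyntheticLesionSpec, generate_cohort,
                                   generate_lesion_record)


@pytest.fixture(scope="session")
def lesion_record():
    """One deterministic synthetic record at desk scale."""
    spec = SyntheticLesionSpec(seed=7)
    return generate_lesion_record(spec, label=1, lesion_id="LES_A")


@pytest.fixture(scope="session")
def small_cohort():
    """60-record cohort with duplicates and a class coverage shift."""
    spec = SyntheticCohortSpec(n_melanoma=30, n_benign=30,
                               duplicate_lesion_fraction=0.2,
                               class_effect=0.1, seed=11)
    return generate_cohort(spec)


def make_record(image, lesion_mask, network_mask, label=1,
                image_id="img", lesion_id="les"):
    """Hand-constructed record from raw arrays (masks as bool)."""
    return LesionRecord(image_id=image_id, lesion_id=lesion_id,
                        image=np.asarray(image, dtype=np.uint8),
                        lesion_mask=np.asarray(lesion_mask, dtype=bool),
                        network_mask=np.asarray(network_mask, dtype=bool),
                        label=label)


@pytest.fixture
def flood_fill_count():
    """Brute-force 8-connected component counter (independent oracle)."""
    def count(mask):
        mask = np.asarray(mask, dtype=bool)
        seen = np.zeros_like(mask)
        sizes = []
        for r0 in range(mask.shape[0]):
            for c0 in range(mask.shape[1]):
                if mask[r0, c0] and not seen[r0, c0]:
                    stack = [(r0, c0)]
                    seen[r0, c0] = True
                    size = 0
                    while stack:
                        r, c = stack.pop()
                        size += 1
                        for dr in (-1, 0, 1):
                            for dc in (-1, 0, 1):
                                rr, cc = r + dr, c + dc
                                if (0 <= rr < mask.shape[0]
                                        and 0 <= cc < mask.shape[1]
                                        and mask[rr, cc]
                                        and not seen[rr, cc]):
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
                    sizes.append(size)
        return sizes
    return count
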