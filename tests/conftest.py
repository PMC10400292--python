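import numpy as np
import pytest

from radgen.harmonization import harmonize
from radgen.roi import Annotation, delineate
from radgen.synthetic import (
    apply_acquisition,
    default_site_profiles,
    generate_phantom,
    sample_phantom_case,
)


@pytest.fixture(scope="session")
def phantom_case():
    """One simulated patient run through acquisition, harmonization and ROI.

    Shared across tests: building it costs a few seconds.
    Returns (spec, annotation_endpoints, nodule, truth_volume, truth_masks,
    harmonized_channels, roi).
    """
    spec, (p0, p1), nod = sample_phantom_case(7)
    truth, masks = generate_phantom(spec, seed=7)
    acquired = apply_acquisition(truth, default_site_profiles()["CHUM"], seed=1)
    channels = harmonize(acquired)
    ann = Annotation("fixture-7", p0, p1)
    roi, chest, lungs = delineate(channels.original, ann)
    return {
        "spec": spec,
        "annotation": ann,
        "nodule": nod,
        "truth": truth,
        "masks": masks,
        "channels": channels,
        "roi": roi,
        "chest": chest,
        "lungs": lungs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
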