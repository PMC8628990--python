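import numpy as np
import pytest

import tierseq as tq
from tierseq.dedup import deduplicate
from tierseq.panel import entry_by_legacy
from tierseq.simulate import PlantedVariant, SampleTruth


@pytest.fixture(scope="session")
def ref():
    return tq.make_reference(1)


@pytest.fixture(scope="session")
def panel(ref):
    return tq.build_default_panel(ref)


@pytest.fixture(scope="session")
def normals(ref):
    return tq.simulate_normals(ref, 12, seed=5)


@pytest.fixture(scope="session")
def het_truth(ref, panel):
    """F508del het + one off-panel exonic SNV + a 5T-12TG carrier tract."""
    f508 = entry_by_legacy(panel, "F508del")
    ex = ref.exons[16]
    pos = (ex.start + ex.end) // 2
    alt = next(b for b in "ACGT" if b != ref.sequence[pos])
    return SampleTruth(
        sample_id="HET1",
        planted_snv_indels=[
            PlantedVariant(f508.pos - 1, f508.ref, f508.alt, "het"),
            PlantedVariant(pos, ref.sequence[pos], alt, "het"),
        ],
        polytgt_diplotype=((12, 5), (11, 7)),
        seed=42,
    )


@pytest.fixture(scope="session")
def het_sample(ref, het_truth):
    return tq.simulate_sample(ref, het_truth)


@pytest.fixture(scope="session")
def het_result(ref, panel, het_sample):
    return tq.run_sample(ref, het_sample, panel)


def small_truth(sample_id="T1", seed=7, fragments=6000, **kw):
    return SampleTruth(sample_id=sample_id, seed=seed,
                       target_unique_fragments=fragments, **kw)


@pytest.fixture()
def small_fragments(ref):
    def make(truth):
        sample = tq.simulate_sample(ref, truth)
        return deduplicate(sample.reads, ref.sequence).fragments
    return make
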