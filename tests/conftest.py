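import pandas as pd
import pytest

from geomxeco.preprocess import (collapse_probes, compute_loq, log2_transform,
                                 q3_normalize, qc_segments)
from geomxeco.synthetic import (SyntheticConfig, generate_reference_assets,
                                generate_segments, reference_phenotype_profiles)


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(config):
    pcm, ann, truth = generate_segments(config)
    return pcm, ann, truth


@pytest.fixture(scope="session")
def assets(config):
    sets, lr, ref, training = generate_reference_assets(config)
    return sets, lr, ref, training


@pytest.fixture(scope="session")
def ne_profiles(config):
    return reference_phenotype_profiles(config)


@pytest.fixture(scope="session")
def preprocessed(dataset):
    """QC-filtered q3 and log2q3 matrices with annotation and LOQ."""
    pcm, ann, _ = dataset
    em_raw = collapse_probes(pcm)
    loq = compute_loq(pcm)
    report, em_raw, ann = qc_segments(em_raw, ann, loq)
    em_q3 = q3_normalize(em_raw, loq=loq)
    em_log = log2_transform(em_q3)
    return {"q3": em_q3, "log2q3": em_log, "ann": ann, "loq": loq,
            "report": report}


@pytest.fixture(scope="session")
def tumor_segments(preprocessed):
    ann = preprocessed["ann"]
    return list(ann.index[ann["compartment"].isin(["tumor", "tumor_only"])])


def make_probe_matrix(probe_rows, seg_names):
    """Build a ProbeCountMatrix from (probe_id, gene, is_neg, counts...) rows."""
    from geomxeco.preprocess import ProbeCountMatrix

    probes = pd.DataFrame(
        {"target_gene": [r[1] for r in probe_rows],
         "is_negative": [r[2] for r in probe_rows]},
        index=pd.Index([r[0] for r in probe_rows], name="probe_id"))
    counts = pd.DataFrame([r[3:] for r in probe_rows],
                          index=probes.index, columns=seg_names)
    return ProbeCountMatrix(probes=probes, counts=counts)
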