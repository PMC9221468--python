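import warnings

import numpy as np
import pandas as pd
import pytest

from pnmine.containers import ExpressionMatrix
from pnmine.pipeline import PipelineConfig, run_pipeline
from pnmine.synthetic import SimConfig, generate_bundle, write_bundle


@pytest.fixture(scope="session")
def small_sim_config():
    return SimConfig(
        n_genes=600,
        n_modules=5,
        module_sizes=[80, 70, 60, 50, 40],
        preserved_flags=[True, True, True, True, False],
        n_cell_lines=10,
        n_tumors=12,
        n_drugs=40,
        seed=2,
    )


@pytest.fixture(scope="session")
def small_bundle(small_sim_config):
    return generate_bundle(small_sim_config)


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    return write_bundle(small_bundle, outdir)


def make_pipeline_config(paths, outdir, seed=9) -> PipelineConfig:
    return PipelineConfig(
        cell_expression=str(paths["cell"]),
        tumor_expression=str(paths["tumor"]),
        screen=str(paths["screen"]),
        annotations=str(paths["annotations"]),
        outdir=str(outdir),
        n_perm=50,
        n_resample=50,
        k_range=[2, 3, 4, 5],
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = make_pipeline_config(bundle_dir, outdir)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(config)
    return config, result


def expr_from_array(values, tag="cell_line", prefix="g"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"{prefix}{i + 1}" for i in range(values.shape[0])],
        columns=[f"s{j + 1}" for j in range(values.shape[1])],
    )
    return ExpressionMatrix(df, tag)
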