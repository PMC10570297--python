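import pathlib

import pytest

from cnvrpop import callset, simulate


@pytest.fixture(scope="session")
def demo_config():
    """The default 7-group x 4-sample demo cohort, fixed seed."""
    return simulate.default_config(seed=11)


@pytest.fixture(scope="session")
def cohort(demo_config, tmp_path_factory):
    """A fully emitted synthetic cohort: truth, files, parsed calls."""
    outdir = tmp_path_factory.mktemp("cohort")
    truth = simulate.generate_truth(demo_config)
    paths = simulate.emit_callset(truth, outdir)
    gene_paths = simulate.emit_genes(demo_config, outdir)
    calls = []
    for sample in demo_config.samples:
        calls.extend(
            callset.read_calls(paths["calls_dir"] / f"{sample}.cnv.tsv", sample)
        )
    return {
        "config": demo_config,
        "truth": truth,
        "outdir": pathlib.Path(outdir),
        "calls": calls,
        **paths,
        **gene_paths,
    }


def make_call(
    sample="s1",
    chrom="chr1",
    start=1001,
    end=5000,
    cnv_type="deletion",
    rd=0.5,
    p=1e-5,
    q0=0.1,
):
    return callset.CNVCall(
        sample_id=sample,
        chrom=chrom,
        start=start,
        end=end,
        cnv_type=cnv_type,
        normalized_rd=rd,
        p_value=p,
        extra_evals=(1e-5, 1e-5, 1e-5),
        q0=q0,
    )
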