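import pytest

from domtrace.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small noise-free paired-temperature dataset with ground truth."""
    return generate_dataset(SyntheticConfig(seed=11, n_formulas=400, ppm_sigma=0.0))


@pytest.fixture
def peak_csv(tmp_path):
    """Factory writing a peak-list CSV and returning its path."""

    def _write(rows, name="peaks.csv", header="mz,intensity"):
        p = tmp_path / name
        lines = [header] + [",".join(str(x) for x in r) for r in rows]
        p.write_text("\n".join(lines) + "\n")
        return p

    return _write
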