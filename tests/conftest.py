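import pytest

from ctdprof.synthetic_data import FamilySpec, generate_family


@pytest.fixture
def small_family():
    """Default-condition family, small species count for speed."""
    return generate_family(FamilySpec(n_species=6, seed=11))


@pytest.fixture
def zero_rate_family():
    """All species identical to the ancestor (substitution rate 0)."""
    return generate_family(FamilySpec(n_species=5, p_sub=0.0, short_isoform_prob=0.0, seed=7))


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
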