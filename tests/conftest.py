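import pytest

from mutamatch import load_table1, load_table2


@pytest.fixture(scope="session")
def table1():
    """The 11 ion-channel genes targeted by approved drugs."""
    return load_table1()


@pytest.fixture(scope="session")
def table2():
    """The 20 GPCR genes targeted by approved drugs."""
    return load_table2()


@pytest.fixture()
def chrom_sizes_file(tmp_path):
    path = tmp_path / "chrom.sizes"
    lines = [f"chr{i}\t{int(l * 1e6)}" for i, l in [
        (1, 248.96), (2, 242.19), (3, 198.30), (7, 159.35),
        (12, 133.28), (21, 46.71),
    ]]
    lines.append("chrX\t156040000")
    path.write_text("\n".join(lines) + "\n")
    return path
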