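import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from repgru.io_formats import ClassMapping, RepeatClass


@pytest.fixture
def class_mapping() -> ClassMapping:
    return ClassMapping.from_items(
        [
            ("HSATII", RepeatClass.HSAT23),
            ("ALR/Alpha", RepeatClass.ALPHOID),
            ("AluY", RepeatClass.ALU),
            ("L1HS", RepeatClass.LINE1),
        ]
    )


@pytest.fixture
def repeatmasker_out(tmp_path):
    """A toy RepeatMasker .out file: 3 header lines, 1-based inclusive
    coordinates, disjoint intervals of all four classes."""
    header = (
        "   SW  perc perc perc  query     position in query    matching repeat\n"
        "score  div. del. ins.  sequence  begin  end  (left)   repeat  class/family\n"
        "\n"
    )
    body_rows = [
        # (begin, end) 1-based inclusive -> 0-based half-open (begin-1, end)
        (101, 200, "AluY", "SINE/Alu"),
        (301, 900, "L1HS", "LINE/L1"),
        (1001, 1500, "ALR/Alpha", "Satellite/centr"),
        (1601, 1700, "HSATII", "Satellite"),
        (1801, 1900, "MER5A", "DNA/hAT"),  # unmapped: must be dropped
    ]
    lines = [
        f" 1000 10.0  0.5  0.5  chr1  {b}  {e}  (0)  +  {name}  {family}  1 100 (0) 1\n"
        for b, e, name, family in body_rows
    ]
    path = tmp_path / "toy.out"
    path.write_text(header + "".join(lines))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
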