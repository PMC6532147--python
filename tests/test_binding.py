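import pytest

from neoepitope import binding
from neoepitope.errors import FormatError, PredictionError
from neoepitope.models import BindingScore


# ---------------------------------------------------------------------------
# predictors


def table():
    return binding.TablePredictor.from_scores([
        BindingScore("SIINFEKL", "HLA-A02:01", 0.4, 30.0),
        BindingScore("SIINFEKL", "HLA-B07:02", 3.5, 800.0),
        BindingScore("KLGGALQAK", "HLA-A02:01", 1.2, 150.0),
        BindingScore("KLGGALQAK", "HLA-B07:02", 0.1, 12.0),
    ])


def test_table_predictor_lookup_and_failure():
    t = table()
    s = t.score("SIINFEKL", "HLA-A02:01")
    assert (s.rank, s.affinity) == (0.4, 30.0)
    with pytest.raises(PredictionError):
        t.score("AAAAAAAA", "HLA-A02:01")


def test_predict_cartesian_contract_with_failures():
    scores, failures = binding.predict(
        ["SIINFEKL", "KLGGALQAK", "MISSING"],
        ["HLA-A02:01", "HLA-B07:02"],
        table(),
    )
    assert len(scores) == 4
    assert len(failures) == 2
    assert {f.peptide for f in failures} == {"MISSING"}


def test_table_predictor_tsv_round_trip(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text(
        "peptide\tallele\trank\taffinity_nM\n"
        "SIINFEKL\tHLA-A02:01\t0.4\t30.0\n"
    )
    t = binding.TablePredictor.from_tsv(p)
    assert t.score("SIINFEKL", "HLA-A02:01") == BindingScore(
        "SIINFEKL", "HLA-A02:01", 0.4, 30.0
    )


def test_hash_predictor_deterministic_in_range():
    h1, h2 = binding.HashPredictor(42), binding.HashPredictor(42)
    other = binding.HashPredictor(43)
    seen = set()
    for pep in ("SIINFEKL", "KLGGALQAK", "AAAAAAAAA"):
        for allele in ("HLA-A01:01", "HLA-B08:01"):
            a, b = h1.score(pep, allele), h2.score(pep, allele)
            assert a == b
            assert 0.0 < a.rank <= 100.0
            assert a.affinity > 1.0
            seen.add(a.rank)
            assert other.score(pep, allele) != a
    assert len(seen) > 1  # not a constant function


# ---------------------------------------------------------------------------
# binder classes


@pytest.mark.parametrize(
    "rank,expected",
    [(0.3, "SB"), (0.49, "SB"), (0.5, "SB"), (0.51, "WB"),
     (1.99, "WB"), (2.0, "WB"), (2.01, "NB"), (50.0, "NB")],
)
def test_classify_binder_inclusive_boundaries(rank, expected):
    assert binding.classify_binder(rank) == expected


def test_classify_binder_monotone_in_rank():
    order = {"SB": 0, "WB": 1, "NB": 2}
    ranks = [0.01 * i for i in range(1, 10000, 37)]
    classes = [order[binding.classify_binder(r)] for r in sorted(ranks)]
    assert classes == sorted(classes)


def test_classify_binder_rejects_out_of_range():
    for bad in (-0.1, 100.5):
        with pytest.raises(ValueError):
            binding.classify_binder(bad)


# ---------------------------------------------------------------------------
# netMHCpan output adapter

NETMHCPAN41 = """\
# NetMHCpan version 4.1b
# Input is in PEPTIDE format
---------------------------------------------------------------------
 Pos         MHC        Peptide      Core Of Gp Gl Ip Il        Icore        Identity  Score_EL %Rank_EL  Score_BA %Rank_BA  Aff(nM) BindLevel
---------------------------------------------------------------------
   1 HLA-A*02:01      SIINFEKL  SIINFEKL- 0  0  0  8  1     SIINFEKL        PEPLIST 0.745000     0.05 0.657000     0.22    30.55 <= SB
   2 HLA-A*02:01     KLGGALQAK  KLGGALQAK 0  0  0  0  0    KLGGALQAK        PEPLIST 0.222000     1.80 0.301000     2.10   812.00 <= WB
---------------------------------------------------------------------
"""

NETMHCPAN40 = """\
# NetMHCpan version 4.0
-----------------------------------------------------------------------------------
  Pos          HLA         Peptide       Core Of Gp Gl Ip Il        Icore        Identity   Score Aff(nM)   %Rank  BindLevel
-----------------------------------------------------------------------------------
    1  HLA-B*07:02       APRGPHGGA  APRGPHGGA  0  0  0  0  0    APRGPHGGA       PEPLIST  0.0621  8899.9   12.00
-----------------------------------------------------------------------------------
"""


def test_parse_netmhcpan_41_prefers_el_rank(tmp_path):
    p = tmp_path / "o.txt"
    p.write_text(NETMHCPAN41)
    scores = binding.parse_netmhcpan(p)
    assert [(s.peptide, s.allele, s.rank, s.affinity) for s in scores] == [
        ("SIINFEKL", "HLA-A02:01", 0.05, 30.55),
        ("KLGGALQAK", "HLA-A02:01", 1.8, 812.0),
    ]


def test_parse_netmhcpan_40_single_rank_column(tmp_path):
    p = tmp_path / "o.txt"
    p.write_text(NETMHCPAN40)
    (s,) = binding.parse_netmhcpan(p)
    assert (s.peptide, s.allele, s.rank, s.affinity) == (
        "APRGPHGGA", "HLA-B07:02", 12.0, 8899.9
    )


def test_parse_netmhcpan_no_data_rows_is_error(tmp_path):
    p = tmp_path / "o.txt"
    p.write_text("# nothing here\n----\n")
    with pytest.raises(FormatError):
        binding.parse_netmhcpan(p)


def test_parse_netmhcpan_malformed_row_names_line(tmp_path):
    p = tmp_path / "o.txt"
    broken = NETMHCPAN41.replace("0.05", "not-a-number")
    p.write_text(broken)
    with pytest.raises(FormatError, match=r":6"):
        binding.parse_netmhcpan(p)


def test_parse_netmhcpan_round_trips_synthetic_scores(tmp_path):
    # write a synthetic long-format file from known scores, reparse exactly
    scores = [
        BindingScore("AAAWAAAW", "HLA-A01:01", 0.37, 55.25),
        BindingScore("CDEFGHIK", "HLA-C07:01", 7.5, 4900.0),
    ]
    lines = [
        " Pos         MHC        Peptide Identity Score_EL %Rank_EL Aff(nM)"
    ]
    for i, s in enumerate(scores, 1):
        allele = s.allele[:5] + "*" + s.allele[5:]
        lines.append(
            f"   {i} {allele} {s.peptide} PEPLIST 0.5 {s.rank} {s.affinity}"
        )
    p = tmp_path / "o.txt"
    p.write_text("\n".join(lines) + "\n")
    assert binding.parse_netmhcpan(p) == scores
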