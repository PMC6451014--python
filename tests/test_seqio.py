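import numpy as np
import pytest

from seqspace.errors import FormatError, ValidationError
from seqspace.seqio import (
    DistanceMatrix,
    Msa,
    read_distance_matrix,
    read_groups,
    read_msa,
    read_newick,
    write_distance_matrix,
    write_msa,
    write_newick,
)


def write(path, text):
    path.write_text(text)
    return str(path)


class TestMsa:
    def test_fasta_parse(self, tmp_path):
        p = write(tmp_path / "a.fasta", ">s1\nAAAA\n>s2\nAATA\n")
        msa = read_msa(p)
        assert msa.n_sites == 4 and msa.n_taxa == 2
        assert msa.rows == ("AAAA", "AATA")

    def test_ragged_rows_name_offender(self, tmp_path):
        p = write(tmp_path / "a.fasta", ">s1\nAAAA\n>s2\nAATAC\n")
        with pytest.raises(ValidationError, match="length"):
            read_msa(p)

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            Msa(("s1", "s1"), ("AAAA", "AATA"))

    def test_illegal_character_reports_position(self, tmp_path):
        p = write(tmp_path / "a.fasta", ">s1\nAABA\n>s2\nAATA\n")
        with pytest.raises(ValidationError, match="'B'.*column 3"):
            read_msa(p)

    def test_case_fold_and_dot_gap(self, tmp_path):
        p = write(tmp_path / "a.fasta", ">s1\naa.a\n>s2\nAATA\n")
        assert read_msa(p).rows[0] == "AA-A"

    @pytest.mark.parametrize("fmt", ["fasta", "phylip", "clustal"])
    def test_roundtrip_identity(self, tmp_path, fmt):
        msa = Msa(("alpha", "beta", "gamma"), ("ACDEF-", "ACDEFX", "AC-EFW"))
        p = str(tmp_path / f"rt.{fmt}")
        write_msa(msa, p, fmt)
        assert read_msa(p) == msa

    def test_auto_detection(self, tmp_path):
        p = write(tmp_path / "x.phy", " 2 4\ns1  AAAA\ns2  AATA\n")
        assert read_msa(p, "auto").n_sites == 4


class TestDistanceMatrixIO:
    def test_phylip_square_format(self, tmp_path):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 0.25], [0.25, 0]]))
        p = str(tmp_path / "d.phy")
        write_distance_matrix(dm, p)
        lines = open(p).read().splitlines()
        assert lines[0].strip() == "2"
        assert lines[1].split()[1:] == ["0.000000", "0.250000"]

    def test_name_truncated_to_ten(self, tmp_path):
        dm = DistanceMatrix(
            ("Arabidopsis_thaliana", "B"), np.array([[0, 0.2], [0.2, 0]])
        )
        p = str(tmp_path / "d.phy")
        write_distance_matrix(dm, p)
        assert open(p).read().splitlines()[1].startswith("Arabidopsi ")

    def test_truncation_collision_is_hard_error(self, tmp_path):
        dm = DistanceMatrix(
            ("Arabidopsis_A", "Arabidopsis_B"), np.array([[0, 0.2], [0.2, 0]])
        )
        with pytest.raises(ValidationError, match="collide"):
            write_distance_matrix(dm, str(tmp_path / "d.phy"))

    @pytest.mark.parametrize("dialect", ["phylip_square", "tsv"])
    def test_write_read_roundtrip(self, tmp_path, dialect, rng):
        n = 5
        m = rng.uniform(0.1, 2.0, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(tuple(f"tax{i}" for i in range(n)), m)
        p = str(tmp_path / "d.txt")
        write_distance_matrix(dm, p, dialect)
        back = read_distance_matrix(p, dialect)
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values, atol=1e-6)

    def test_lower_triangle_accepted(self, tmp_path):
        p = write(tmp_path / "lt.phy", "    3\nA\nB 0.400000\nC 0.600000 0.800000\n")
        dm = read_distance_matrix(p)
        assert dm.get("A", "B") == pytest.approx(0.4)
        assert dm.get("B", "C") == pytest.approx(0.8)

    def test_count_mismatch(self, tmp_path):
        p = write(tmp_path / "bad.phy", "    3\nA 0.0 0.1 0.2\nB 0.1 0.0 0.3\n")
        with pytest.raises(FormatError, match="3 taxa"):
            read_distance_matrix(p)

    def test_negative_entry(self, tmp_path):
        p = write(tmp_path / "neg.phy", "    2\nA 0.0 -0.1\nB -0.1 0.0\n")
        with pytest.raises(ValidationError, match="negative"):
            read_distance_matrix(p)

    def test_large_asymmetry_rejected(self, tmp_path):
        p = write(tmp_path / "asym.phy", "    2\nA 0.0 0.10\nB 0.11 0.0\n")
        with pytest.raises(ValidationError, match="asymmetry"):
            read_distance_matrix(p)


class TestNewick:
    def test_two_leaf_roundtrip(self):
        t = read_newick("(A:1,B:2);")
        assert sorted(t.leaf_names()) == ["A", "B"]
        assert t.total_length() == pytest.approx(3.0)
        again = read_newick(write_newick(t))
        assert sorted(again.leaf_names()) == ["A", "B"]
        assert again.total_length() == pytest.approx(3.0)

    def test_internal_support_parsed(self):
        t = read_newick("((A:1,B:2)0.95:1,C:3);")
        internal = [n for n in t.postorder() if not n.is_leaf and n.parent is not None]
        assert internal[0].support == pytest.approx(0.95)
        assert "0.95" in write_newick(t)

    def test_non_numeric_internal_label_kept_as_name(self):
        t = read_newick("((A:1,B:2)cladeX:1,C:3);")
        internal = [n for n in t.postorder() if not n.is_leaf and n.parent is not None]
        assert internal[0].support is None
        assert internal[0].name == "cladeX"

    def test_unbalanced_parens(self):
        with pytest.raises(FormatError):
            read_newick("((A:1,B:2;")

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            read_newick("(A:1,A:2);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            read_newick("(A:1,B:-2);")


class TestGroups:
    def test_read_groups(self, tmp_path):
        p = write(tmp_path / "g.tsv", "taxA\tslow\ntaxB\tfast\t#d62728\n")
        ann = read_groups(p)
        assert ann.groups == {"taxA": "slow", "taxB": "fast"}
        assert ann.colors == {"fast": "#d62728"}

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = write(tmp_path / "g.tsv", "taxA\tslow\ntaxA\tfast\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_groups(p)
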