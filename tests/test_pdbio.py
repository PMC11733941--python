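import pytest

from dmdgp.encoding import encode, reduce
from dmdgp.geometry import dist
from dmdgp.pdbio import (parse_first_model, segment_to_conformation,
                         segmentize, segments_manifest, write_fixture_pdb)
from dmdgp.synthetic import sample_conformation

# synthetic fixtures have no amide H on residue 1 (a real N-terminus has
# H1/H2/H3 instead), so segment extraction starts at residue 2


def _fixture_text(tmp_path, conf, name="fix.pdb"):
    path = tmp_path / name
    write_fixture_pdb(conf, path)
    return path.read_text()


def _match_residue_atoms(conf, residues, tol=1.8e-3):
    """Every parsed atom sits on its order vertex to PDB precision."""
    for rec in residues:
        for kind, p in rec.atoms.items():
            pos = conf.order.position_of(kind, rec.resseq)
            assert dist(p, conf.point(pos)) <= tol


class TestFixtureWriter:
    def test_atom_count_excludes_repeats_and_first_h(self, params_jitter,
                                                     tmp_path):
        conf = sample_conformation(3, params_jitter, seed=1)
        text = _fixture_text(tmp_path, conf)
        atom_lines = [l for l in text.splitlines() if l.startswith("ATOM")]
        # 15 order slots - 1 repeated CA = 14 distinct atoms
        assert len(atom_lines) == 14

    def test_fixed_width_columns(self, params_jitter, tmp_path):
        conf = sample_conformation(3, params_jitter, seed=1)
        for line in _fixture_text(tmp_path, conf).splitlines():
            if not line.startswith("ATOM"):
                continue
            assert len(line) >= 78
            int(line[6:11])          # serial
            assert line[17:20] == "ALA"
            assert line[21] == "A"
            int(line[22:26])         # resseq
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
            assert line[76:78].strip() in ("N", "C", "H")

    def test_write_then_parse_round_trip(self, params_jitter, tmp_path):
        conf = sample_conformation(4, params_jitter, seed=7)
        residues = parse_first_model(_fixture_text(tmp_path, conf))
        assert len(residues) == 4
        assert [r.complete for r in residues] == [False, True, True, True]
        _match_residue_atoms(conf, residues)

    def test_bits_survive_pdb_rounding(self, params_jitter, tmp_path):
        """1e-3 A coordinate rounding does not move any free bit."""
        conf = sample_conformation(5, params_jitter, seed=8)
        residues = parse_first_model(_fixture_text(tmp_path, conf))
        seg = segmentize(residues, "fix")[0]
        rounded = segment_to_conformation(seg)
        # rebuild the unrounded sub-conformation over the same residues
        exact = sample_conformation(5, params_jitter, seed=8)
        sub = segment_to_conformation(
            type(seg)(seg.source_id, seg.chain, tuple(
                type(r)(r.chain, r.resseq, r.icode, r.resname,
                        {k: exact.point(exact.order.position_of(k, r.resseq))
                         for k in r.atoms})
                for r in seg.residues)))
        assert reduce(encode(rounded, tol=1e-3)).as_str() == \
            reduce(encode(sub, tol=1e-3)).as_str()


class TestParseFirstModel:
    def test_only_first_model_kept(self, params_jitter, tmp_path):
        c1 = sample_conformation(3, params_jitter, seed=1)
        c2 = sample_conformation(3, params_jitter, seed=2)
        t1 = _fixture_text(tmp_path, c1, "a.pdb")
        t2 = _fixture_text(tmp_path, c2, "b.pdb")
        body2 = "\n".join(
            l for l in t2.splitlines() if l.startswith(("ATOM", "TER")))
        merged = t1.replace("ENDMDL",
                            "ENDMDL\nMODEL        2\n" + body2 + "\nENDMDL")
        residues = parse_first_model(merged)
        _match_residue_atoms(c1, residues)

    def test_non_backbone_atoms_filtered(self, params_jitter, tmp_path):
        conf = sample_conformation(3, params_jitter, seed=1)
        text = _fixture_text(tmp_path, conf)
        cb = ("ATOM   9999  CB  ALA A   2      1.000   2.000   3.000"
              "  1.00  0.00           C")
        text = text.replace("TER", cb + "\nTER")
        residues = parse_first_model(text)
        assert all("CB" not in r.atoms for r in residues)

    def test_no_atoms_warns_not_raises(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert parse_first_model("HEADER    EMPTY\nEND\n") == []


class TestSegmentize:
    def test_gly_splits_chain(self, params_jitter, tmp_path):
        conf = sample_conformation(6, params_jitter, seed=3)
        text = _fixture_text(tmp_path, conf)
        text = text.replace("ALA A   4", "GLY A   4")
        segments = segmentize(parse_first_model(text), "x")
        # residue 1 lacks H, GLY 4 removed: runs are (2,3) and (5,6)
        assert [len(s) for s in segments] == [2, 2]

    def test_missing_hydrogen_breaks_segment(self, params_jitter, tmp_path):
        conf = sample_conformation(6, params_jitter, seed=3)
        lines = _fixture_text(tmp_path, conf).splitlines()
        lines = [l for l in lines
                 if not (l.startswith("ATOM") and l[13:15].strip() == "H"
                         and int(l[22:26]) == 4)]
        segments = segmentize(parse_first_model("\n".join(lines)), "x")
        assert [len(s) for s in segments] == [2, 2]

    def test_numbering_gap_breaks_segment(self, params_jitter, tmp_path):
        conf = sample_conformation(5, params_jitter, seed=3)
        text = _fixture_text(tmp_path, conf)
        text = text.replace("ALA A   5", "ALA A   7")
        segments = segmentize(parse_first_model(text), "x")
        # complete residues 2,3,4,7 -> run (2,3,4); singleton 7 dropped
        assert [len(s) for s in segments] == [3]

    def test_complete_run_is_one_segment(self, params_jitter, tmp_path):
        conf = sample_conformation(5, params_jitter, seed=4)
        segments = segmentize(
            parse_first_model(_fixture_text(tmp_path, conf)), "x")
        assert len(segments) == 1
        assert (segments[0].start, segments[0].end) == (2, 5)

    def test_manifest_csv(self, params_jitter, tmp_path):
        import pandas as pd
        conf = sample_conformation(4, params_jitter, seed=4)
        segments = segmentize(
            parse_first_model(_fixture_text(tmp_path, conf)), "src")
        segments_manifest(segments, tmp_path / "manifest.csv")
        df = pd.read_csv(tmp_path / "manifest.csv")
        assert list(df.columns) == ["source_id", "chain", "start", "end",
                                    "length"]
        assert df.iloc[0]["length"] == 3
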