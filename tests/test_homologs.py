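import filecmp
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synaln.core_io import Sequence
from synaln.errors import ConsistencyError, ParameterError
from synaln.homologs import (
    FamilySimulation,
    HomologMember,
    HomologSet,
    filter_homologs,
    parse_psiblast,
    simulate_family,
    write_psiblast_text,
)

BLAST_XML_TEMPLATE = """<?xml version="1.0"?>
<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">
<BlastOutput>
  <BlastOutput_program>blastp</BlastOutput_program>
  <BlastOutput_version>BLASTP 2.2.26+</BlastOutput_version>
  <BlastOutput_reference>ref</BlastOutput_reference>
  <BlastOutput_db>nr</BlastOutput_db>
  <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>
  <BlastOutput_query-def>S</BlastOutput_query-def>
  <BlastOutput_query-len>{qlen}</BlastOutput_query-len>
  <BlastOutput_param>
    <Parameters>
      <Parameters_matrix>BLOSUM62</Parameters_matrix>
      <Parameters_expect>10</Parameters_expect>
      <Parameters_gap-open>11</Parameters_gap-open>
      <Parameters_gap-extend>1</Parameters_gap-extend>
      <Parameters_filter>F</Parameters_filter>
    </Parameters>
  </BlastOutput_param>
  <BlastOutput_iterations>
    <Iteration>
      <Iteration_iter-num>1</Iteration_iter-num>
      <Iteration_query-ID>Query_1</Iteration_query-ID>
      <Iteration_query-def>S</Iteration_query-def>
      <Iteration_query-len>{qlen}</Iteration_query-len>
      <Iteration_hits>{hits}</Iteration_hits>
    </Iteration>
  </BlastOutput_iterations>
</BlastOutput>
"""

HIT_TEMPLATE = """
        <Hit>
          <Hit_num>{num}</Hit_num>
          <Hit_id>{hid}</Hit_id>
          <Hit_def>{hid}</Hit_def>
          <Hit_accession>{hid}</Hit_accession>
          <Hit_len>{hlen}</Hit_len>
          <Hit_hsps>{hsps}</Hit_hsps>
        </Hit>"""

HSP_TEMPLATE = """
            <Hsp>
              <Hsp_num>{num}</Hsp_num>
              <Hsp_bit-score>40</Hsp_bit-score>
              <Hsp_score>90</Hsp_score>
              <Hsp_evalue>1e-9</Hsp_evalue>
              <Hsp_query-from>{qfrom}</Hsp_query-from>
              <Hsp_query-to>{qto}</Hsp_query-to>
              <Hsp_hit-from>{hfrom}</Hsp_hit-from>
              <Hsp_hit-to>{hto}</Hsp_hit-to>
              <Hsp_identity>{ident}</Hsp_identity>
              <Hsp_positive>{ident}</Hsp_positive>
              <Hsp_gaps>0</Hsp_gaps>
              <Hsp_align-len>{alen}</Hsp_align-len>
              <Hsp_qseq>{qseq}</Hsp_qseq>
              <Hsp_hseq>{hseq}</Hsp_hseq>
              <Hsp_midline>{mid}</Hsp_midline>
            </Hsp>"""


def make_xml(qlen, hits):
    hit_blocks = []
    for num, (hid, hlen, hsps) in enumerate(hits, 1):
        hsp_blocks = []
        for hnum, h in enumerate(hsps, 1):
            hsp_blocks.append(HSP_TEMPLATE.format(num=hnum, mid=" " * h["alen"], **h))
        hit_blocks.append(
            HIT_TEMPLATE.format(num=num, hid=hid, hlen=hlen, hsps="".join(hsp_blocks))
        )
    return BLAST_XML_TEMPLATE.format(qlen=qlen, hits="".join(hit_blocks))


class TestParsePsiblastXml:
    target = Sequence("S", "ACDEFGHIKLMNPQRSTVWY")

    def hsp(self, qfrom, qto, hfrom, hto, qseq, hseq, ident):
        return dict(
            qfrom=qfrom, qto=qto, hfrom=hfrom, hto=hto,
            qseq=qseq, hseq=hseq, ident=ident, alen=len(qseq),
        )

    def test_single_hsp_identity_from_stated_fields(self, tmp_path):
        # 12 identities over 20 columns -> 60.0
        xml = make_xml(20, [
            ("h1", 20, [self.hsp(1, 20, 1, 20, self.target.residues,
                                 self.target.residues, 12)]),
        ])
        p = tmp_path / "b.xml"
        p.write_text(xml)
        hs = parse_psiblast(p, self.target, "xml")
        assert len(hs.members) == 1
        assert hs.members[0].identity == pytest.approx(60.0)
        assert hs.members[0].alignment.pairs[0] == (0, 0)

    def test_two_hsps_become_two_members(self, tmp_path):
        xml = make_xml(20, [
            ("h1", 30, [
                self.hsp(1, 10, 1, 10, self.target.residues[:10],
                         self.target.residues[:10], 10),
                self.hsp(11, 20, 21, 30, self.target.residues[10:],
                         self.target.residues[10:], 10),
            ]),
        ])
        p = tmp_path / "b.xml"
        p.write_text(xml)
        hs = parse_psiblast(p, self.target, "xml")
        assert len(hs.members) == 2
        # local offsets preserved: second HSP starts at query residue 10
        assert hs.members[1].alignment.pairs[0] == (10, 20)

    def test_empty_hit_list(self, tmp_path):
        p = tmp_path / "b.xml"
        p.write_text(make_xml(20, []))
        hs = parse_psiblast(p, self.target, "xml")
        assert hs.members == []

    def test_query_length_mismatch(self, tmp_path):
        p = tmp_path / "b.xml"
        p.write_text(make_xml(19, []))
        with pytest.raises(ConsistencyError):
            parse_psiblast(p, self.target, "xml")


class TestParsePsiblastText:
    def test_write_parse_fixed_point(self, tmp_path, rng):
        from conftest import random_homolog_set, random_sequence

        target = random_sequence(rng, "S", 40)
        hs = random_homolog_set(rng, target, 4)
        p1 = tmp_path / "r1.txt"
        write_psiblast_text(hs, p1)
        hs2 = parse_psiblast(p1, target, "pairwise_text")
        p2 = tmp_path / "r2.txt"
        write_psiblast_text(hs2, p2)
        assert p1.read_text() == p2.read_text()
        assert [m.alignment.pairs for m in hs2.members] == [
            m.alignment.pairs for m in hs.members
        ]

    def test_parses_local_offsets(self, tmp_path):
        target = Sequence("S", "ACDEFGHIKL")
        text = (
            "Query= S\n\nLength=10\n\n"
            ">hom1\nLength=9\n\n"
            " Score = 20.0 bits (40),  Expect = 1e-05\n"
            " Identities = 4/5 (80%)\n\n"
            "Query  3  DEFGH  7\n"
            "Sbjct  5  DEWGH  9\n\n"
        )
        p = tmp_path / "r.txt"
        p.write_text(text)
        hs = parse_psiblast(p, target, "pairwise_text")
        assert len(hs.members) == 1
        m = hs.members[0]
        assert m.identity == pytest.approx(80.0)
        assert m.alignment.pairs == [(2, 4), (3, 5), (4, 6), (5, 7), (6, 8)]


class TestFilterHomologs:
    def make(self, identities):
        from synaln.core_io import PairwiseAlignment

        t = Sequence("S", "ACDEF")
        members = [
            HomologMember(
                f"h{k}", PairwiseAlignment("S", f"h{k}", "ACDEF", "ACDEF"), ident
            )
            for k, ident in enumerate(identities)
        ]
        return HomologSet(t, members)

    def test_boundary_is_inclusive(self):
        hs = filter_homologs(self.make([25, 30, 55]), 30)
        assert [m.identity for m in hs.members] == [30, 55]

    def test_threshold_zero_keeps_all(self):
        hs = self.make([25, 30, 55])
        assert filter_homologs(hs, 0).members == hs.members

    def test_all_below_threshold_is_valid(self):
        assert filter_homologs(self.make([5, 10]), 30).members == []

    @given(st.lists(st.floats(0, 100), max_size=8), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, identities, threshold):
        hs = self.make(identities)
        once = filter_homologs(hs, threshold)
        twice = filter_homologs(once, threshold)
        assert [m.identity for m in once.members] == [
            m.identity for m in twice.members
        ]


class TestSimulateFamily:
    def test_deterministic_given_seed(self, tmp_path):
        a = simulate_family(ancestor_length=60, n_homologs=3, seed=11)
        b = simulate_family(ancestor_length=60, n_homologs=3, seed=11)
        assert a.targets == b.targets
        assert a.true_pairs == b.true_pairs
        d1, d2 = tmp_path / "d1", tmp_path / "d2"
        a.save(d1)
        b.save(d2)
        for f in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_no_indels_truth_is_identity_map(self):
        sim = simulate_family(ancestor_length=50, n_homologs=2, indel_rate=0.0, seed=3)
        assert sim.pair_truth("S", "T") == [(i, i) for i in range(50)]

    def test_full_identity_homologs_equal_target(self):
        sim = simulate_family(
            ancestor_length=40, n_homologs=3, homolog_identity=100.0,
            indel_rate=0.0, seed=5,
        )
        for m in sim.homologs_s.members:
            assert m.alignment.ungapped_b == sim.targets[0].residues
            assert m.identity == pytest.approx(100.0)

    def test_identity_100_with_indels_rejected(self):
        with pytest.raises(ParameterError):
            simulate_family(homolog_identity=100.0, indel_rate=0.1)

    def test_short_ancestor_rejected(self):
        with pytest.raises(ParameterError):
            simulate_family(ancestor_length=10)

    def test_realized_homolog_identity_within_band(self):
        sim = simulate_family(seed=2)
        for hs in sim.homolog_sets.values():
            for m in hs.members:
                assert abs(m.identity - 60.0) <= 10.0

    def test_mean_pair_identity_tracks_request(self):
        # 25 seeds at the twilight settings: mean realized identity in 15 +- 5
        from synaln.evaluation import seq_identity
        from synaln.protocols import truth_alignment

        idents = []
        for seed in range(25):
            sim = simulate_family(seed=seed)
            idents.append(seq_identity(truth_alignment(sim, "S", "T")))
        assert 10.0 <= float(np.mean(idents)) <= 20.0

    def test_save_load_round_trip(self, tmp_path):
        sim = simulate_family(ancestor_length=50, n_homologs=3, seed=9)
        sim.save(tmp_path / "fam")
        back = FamilySimulation.load(tmp_path / "fam")
        assert back.targets == sim.targets
        assert back.true_pairs == {
            k: [tuple(p) for p in v] for k, v in sim.true_pairs.items()
        }
        for tid, hs in sim.homolog_sets.items():
            bhs = back.homolog_sets[tid]
            assert [m.alignment.pairs for m in bhs.members] == [
                m.alignment.pairs for m in hs.members
            ]

    def test_multi_target_family(self):
        sim = simulate_family(ancestor_length=40, n_targets=4, n_homologs=2, seed=1)
        assert len(sim.targets) == 4
        assert len(sim.true_pairs) == 6
        assert sim.pair_truth("U", "S") == [
            (j, i) for (i, j) in sim.pair_truth("S", "U")
        ]
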