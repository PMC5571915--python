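import warnings

import numpy as np
import pytest

from dockint.classify import LocationLabel
from dockint.fixtures import table2_census
from dockint.nip import NIPProfile
from dockint.sasa import ASAProfile
from dockint.structures import ResidueKey
from dockint.variants import (
    AlignmentError,
    Evidence,
    VariantAnnotation,
    VariantCategory,
    VariantRecord,
    annotate_variants,
    build_numbering_map,
    census,
    parse_variant_table,
)

from conftest import build_model

HUMSAVAR_FIXTURE = """\
ELANE     P08246      VAR_000001  p.Ile104Asn    Disease      rs000001     Cyclic hematopoiesis (CH) [MIM:162800]
TOY1      P99999      VAR_000002  p.Arg12His     Disease      -            Synthetic disorder [MIM:000000]
TOY1      P99999      VAR_000003  p.Ala3Val      Polymorphism -            -
TOY1      P99999      VAR_000004  p.Gly7Ser      Polymorphism rs000002     -
TOY1      P99999      VAR_000005  p.Leu2Phe      Unclassified -            -
TOY1      P99999      VAR_000006  p.Lys9Glu      Unclassified -            -
"""


class TestParseVariantTable:
    def test_disease_substitution(self):
        recs = parse_variant_table(HUMSAVAR_FIXTURE)
        first = recs[0]
        assert (first.position, first.wt_aa, first.mut_aa) == (104, "I", "N")
        assert first.category is VariantCategory.DISEASE
        assert "MIM:162800" in first.phenotype_text

    def test_category_counts(self):
        recs = parse_variant_table(HUMSAVAR_FIXTURE)
        counts = {c: sum(r.category is c for r in recs)
                  for c in VariantCategory}
        assert counts == {VariantCategory.DISEASE: 2,
                          VariantCategory.POLYMORPHISM: 2,
                          VariantCategory.UNCLASSIFIED: 2}

    def test_silent_substitution_rejected(self):
        line = "TOY1 P99999 VAR_1 p.Ala10Ala Disease - -\n"
        with pytest.warns(UserWarning, match="silent"):
            recs = parse_variant_table(line)
        assert recs == []
        with pytest.raises(ValueError):
            parse_variant_table(line, strict=True)

    def test_unparseable_substitution_skipped(self):
        line = "TOY1 P99999 VAR_1 p.Met1? Disease - -\n"
        with pytest.warns(UserWarning, match="unparseable"):
            assert parse_variant_table(line) == []

    def test_header_lines_ignored(self):
        text = "Gene  AC  FTId  Change  Type  dbSNP  Disease\n" \
            + HUMSAVAR_FIXTURE
        assert len(parse_variant_table(text)) == 6

    def test_modern_vocabulary_behind_flag(self):
        line = "TOY1 P99999 VAR_1 p.Ala10Val LP/P - -\n"
        assert parse_variant_table(line) == []
        recs = parse_variant_table(line, allow_modern_vocabulary=True)
        assert recs[0].category is VariantCategory.DISEASE

    def test_silent_record_invariant(self):
        with pytest.raises(ValueError):
            VariantRecord("P1", 10, "A", "A", VariantCategory.DISEASE)


def chain_model(names, first_number=1):
    residues = [[(4.0 * i, 0.0, 0.0)] for i in range(len(names))]
    m = build_model(residues, names=names)
    # renumber to simulate author numbering offsets
    m.residues = [ResidueKey("A", first_number + i, "", k.name)
                  for i, k in enumerate(m.residues)]
    m._residue_index = {k: i for i, k in enumerate(m.residues)}
    return m


SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
NAMES3 = {"M": "MET", "K": "LYS", "T": "THR", "A": "ALA", "Y": "TYR",
          "I": "ILE", "Q": "GLN", "R": "ARG", "S": "SER", "F": "PHE",
          "V": "VAL", "H": "HIS", "L": "LEU", "E": "GLU", "G": "GLY"}


class TestBuildNumberingMap:
    def test_identity_numbering(self):
        m = chain_model([NAMES3[c] for c in SEQ])
        nm = build_numbering_map(SEQ, m, accession="P1")
        assert nm.identity == 1.0
        for pos, key in nm.mapping.items():
            assert key.number == pos

    def test_shifted_numbering_recovered(self):
        # structure covers sequence positions 5..20, numbered 29..44 (+24)
        sub = SEQ[4:20]
        m = chain_model([NAMES3[c] for c in sub], first_number=29)
        nm = build_numbering_map(SEQ, m, accession="P1")
        for pos in range(5, 21):
            assert nm.mapping[pos].number == pos + 24
        # round trip through the inverse
        inv = nm.inverse()
        assert all(inv[nm.mapping[p]] == p for p in nm.mapping)

    def test_unrelated_sequence_rejected(self):
        m = chain_model(["GLY"] * 20)
        with pytest.raises(AlignmentError) as err:
            build_numbering_map(SEQ, m, accession="P1")
        assert err.value.alignment is not None


def _rasa_profile(model, rasa):
    return ASAProfile(residues=list(model.residues),
                      asa=np.asarray(rasa) * 100.0,
                      rasa=np.asarray(rasa, dtype=float),
                      atom_asa=np.zeros(model.n_atoms), probe_radius=1.4,
                      n_points=960, source_id=model.source_id)


class TestAnnotateVariants:
    def setup_method(self):
        self.seq = "MKTAY"
        self.model = chain_model([NAMES3[c] for c in self.seq])
        self.model.source_id = "struct1"
        self.nm = build_numbering_map(self.seq, self.model, accession="P1")
        self.maps = {"P1": [self.nm]}
        self.keys = self.model.residues
        self.rasa = {"struct1": _rasa_profile(self.model,
                                              [0.5, 0.05, 0.5, 0.5, 0.5])}

    def _variant(self, pos, wt, mut="W", cat=VariantCategory.DISEASE):
        return VariantRecord("P1", pos, wt, mut, cat)

    def _nip(self, ext, hot_nip=None):
        nip = np.zeros(len(self.keys))
        if hot_nip:
            for key, v in hot_nip.items():
                nip[self.keys.index(key)] = v
        return NIPProfile(residues=list(self.keys),
                          abs_values=np.zeros(len(self.keys)), nip=nip,
                          hotspots={k for k, v in (hot_nip or {}).items()
                                    if v >= 0.2},
                          extended_interface=set(ext), n_poses_used=100)

    def test_structure_interface_evidence(self):
        labels = {"struct1": {self.keys[0]: LocationLabel.INTERFACE}}
        anns = annotate_variants([self._variant(1, "M")], self.maps, labels,
                                 rasa_profiles=self.rasa)
        assert anns[0].location is LocationLabel.INTERFACE
        assert anns[0].evidence is Evidence.STRUCTURE

    def test_docking_patch_upgrades_surface_to_interface(self):
        labels = {"struct1": {
            self.keys[0]: LocationLabel.NON_INTERFACE_SURFACE}}
        prof = self._nip(ext=[self.keys[0]])
        anns = annotate_variants([self._variant(1, "M")], self.maps, labels,
                                 {"struct1": prof}, self.rasa)
        assert anns[0].location is LocationLabel.INTERFACE
        assert anns[0].evidence is Evidence.DOCKING

    def test_both_sources(self):
        labels = {"struct1": {self.keys[0]: LocationLabel.INTERFACE}}
        prof = self._nip(ext=[self.keys[0]])
        anns = annotate_variants([self._variant(1, "M")], self.maps, labels,
                                 {"struct1": prof}, self.rasa)
        assert anns[0].evidence is Evidence.BOTH

    def test_hotspot_requires_interface_and_nip(self):
        prof = self._nip(ext=[self.keys[0]], hot_nip={self.keys[0]: 0.5})
        anns = annotate_variants([self._variant(1, "M")], self.maps, {},
                                 {"struct1": prof}, self.rasa)
        assert anns[0].hotspot is True
        assert anns[0].location is LocationLabel.INTERFACE

    def test_core_from_average_rasa(self):
        anns = annotate_variants([self._variant(2, "K")], self.maps, {},
                                 rasa_profiles=self.rasa)
        assert anns[0].location is LocationLabel.CORE

    def test_position_outside_structures_unmapped(self):
        anns = annotate_variants([self._variant(9999, "A")], self.maps, {},
                                 rasa_profiles=self.rasa)
        assert anns[0].location is None
        assert anns[0].evidence is Evidence.NONE

    def test_wild_type_mismatch_unmapped_with_warning(self):
        with pytest.warns(UserWarning, match="wild type"):
            anns = annotate_variants([self._variant(1, "Q")], self.maps, {},
                                     rasa_profiles=self.rasa)
        assert anns[0].location is None
        with pytest.raises(ValueError):
            annotate_variants([self._variant(1, "Q")], self.maps, {},
                              rasa_profiles=self.rasa, strict=True)

    def test_hotspot_invariant_enforced(self):
        rec = self._variant(1, "M")
        with pytest.raises(ValueError):
            VariantAnnotation(rec, LocationLabel.CORE, True,
                              Evidence.STRUCTURE)


class TestCensus:
    def _annotation(self, pos, cat, location, hotspot=False):
        rec = VariantRecord("P1", pos, "A", "V", cat)
        ev = Evidence.NONE if location is None else Evidence.STRUCTURE
        return VariantAnnotation(rec, location, hotspot, ev)

    def test_empty_annotations_zero_counts(self):
        labels = {ResidueKey("A", 1, "", "ALA"): LocationLabel.CORE}
        c = census([], labels)
        assert c.total_snps == 0
        assert c.residue_counts["core"] == 1

    def test_hand_tally(self):
        keys = [ResidueKey("A", i, "", "ALA") for i in range(1, 11)]
        labels = {k: LocationLabel.CORE for k in keys[:3]}
        labels.update({k: LocationLabel.INTERFACE for k in keys[3:7]})
        labels.update({k: LocationLabel.NON_INTERFACE_SURFACE
                       for k in keys[7:]})
        D, P = VariantCategory.DISEASE, VariantCategory.POLYMORPHISM
        anns = (
            [self._annotation(i, D, LocationLabel.CORE) for i in (1, 2)]
            + [self._annotation(4, D, LocationLabel.INTERFACE, hotspot=True)]
            + [self._annotation(5, D, LocationLabel.INTERFACE)]
            + [self._annotation(8, D, LocationLabel.NON_INTERFACE_SURFACE)]
            + [self._annotation(6, P, LocationLabel.INTERFACE)]
            + [self._annotation(9, P, None)]
        )
        c = census(anns, labels, hotspot_residues={keys[3]})
        dis = c.snp_counts[D]
        assert dis == {"core": 2, "interface": 2, "non_interface": 1,
                       "interface_hotspot": 1}
        assert c.snp_counts[P]["interface"] == 1
        assert c.unmapped[P] == 1
        assert c.residue_counts == {
            "total": 10, "core": 3, "interface": 4, "non_interface": 3,
            "hotspot": 1, "hotspot_at_interface": 1}

    def test_order_invariance(self):
        keys = [ResidueKey("A", i, "", "ALA") for i in range(1, 6)]
        labels = {k: LocationLabel.INTERFACE for k in keys}
        anns = [self._annotation(i, VariantCategory.DISEASE,
                                 LocationLabel.INTERFACE)
                for i in range(1, 6)]
        a = census(anns, labels)
        b = census(list(reversed(anns)), labels)
        assert a.snp_counts == b.snp_counts


class TestPackagedCensus:
    def test_structural_totals(self):
        c = table2_census("structural")
        assert c.snp_total(VariantCategory.DISEASE) == 832
        assert c.snp_total(VariantCategory.POLYMORPHISM) == 499
        assert c.snp_total(VariantCategory.UNCLASSIFIED) == 293
        assert c.total_snps == 1624

    def test_docking_total(self):
        assert table2_census("docking").total_snps == 2615

    def test_combined_hotspot_disease(self):
        c = table2_census("combined")
        assert c.snp_counts[VariantCategory.DISEASE]["interface_hotspot"] == 109

    def test_invariants_hold_in_all_contexts(self):
        for ctx in ("structural", "docking", "combined"):
            c = table2_census(ctx)
            rc = c.residue_counts
            assert rc["core"] + rc["interface"] + rc["non_interface"] == \
                rc["total"]
            assert rc["hotspot_at_interface"] <= rc["interface"]

    def test_unknown_context_is_error(self):
        with pytest.raises(KeyError):
            table2_census("bogus")

    def test_combined_interface_counts_dominate(self):
        # union rule: combining contexts can only add interface variants
        s = table2_census("structural")
        comb = table2_census("combined")
        for cat in VariantCategory:
            assert comb.snp_counts[cat]["interface"] >= \
                s.snp_counts[cat]["interface"]
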