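"""Locus-detection rules: chaining, screens, expansion, finalization, and
end-to-end behaviour on genomes with planted ground truth."""

import dataclasses

import pytest

from ecisminer.core_roles import assign_core_roles
from ecisminer.loci import (
    CandidateLocus,
    chain_seed_groups,
    collect_seed_genes,
    contamination_screen,
    detect_loci,
    detect_loci_report,
    expand_group,
    finalize_locus,
    seed_filter,
)
from ecisminer.model import GeneRecord, HmmHit
from ecisminer.simulate import PlantSpec, make_genome, standard_plant_mixture


def seed_gene(factory, i, start, pfam="PF14065", **kw):
    return factory(f"g{i}", start, start + 899, pfams={pfam}, **kw)


class TestSeedCollectionAndChaining:
    def test_only_ecis_pfams_are_seeds(self, config, gene_factory):
        genes = [
            gene_factory("a", 1, 900, pfams={"PF14065"}),
            gene_factory("b", 1000, 1900, pfams={"PF99999"}),
            gene_factory("c", 2000, 2900),
            gene_factory("d", 3000, 3900, pfams={"PF04984"}, coding=False),
        ]
        assert [g.gene_id for g in collect_seed_genes(genes, config)] == ["a"]

    def test_gap_over_threshold_splits(self, config, gene_factory):
        # gaps: 5,000 then 13,000
        s1 = seed_gene(gene_factory, 1, 1)
        s2 = seed_gene(gene_factory, 2, s1.end + 5001)
        s3 = seed_gene(gene_factory, 3, s2.end + 13001)
        groups = chain_seed_groups([s1, s2, s3], 12_000, config)
        assert [len(g.members) for g in groups] == [2, 1]

    def test_gap_exactly_at_threshold_is_inclusive(self, config, gene_factory):
        s1 = seed_gene(gene_factory, 1, 1)
        s2 = seed_gene(gene_factory, 2, s1.end + 12_001)  # gap == 12,000
        (group,) = chain_seed_groups([s1, s2], 12_000, config)
        assert len(group.members) == 2

    def test_scaffolds_never_co_group(self, config, gene_factory):
        s1 = seed_gene(gene_factory, 1, 1, scaffold="sA")
        s2 = seed_gene(gene_factory, 2, 1000, scaffold="sB")
        assert len(chain_seed_groups([s1, s2], 12_000, config)) == 2


class TestSeedFilter:
    def group(self, config, gene_factory, pfams):
        seeds = [
            seed_gene(gene_factory, i, 1 + i * 1500, pfam=p)
            for i, p in enumerate(pfams)
        ]
        (g,) = chain_seed_groups(seeds, 12_000, config)
        return g

    def test_boundary_accept(self, config, gene_factory):
        g = self.group(config, gene_factory,
                       ["PF14065", "PF04984", "PF06841", "PF06841"])
        assert seed_filter(g, config) == (True, None)

    def test_one_shared_pfam_rejected(self, config, gene_factory):
        g = self.group(config, gene_factory, ["PF14065"] * 5)
        ok, reason = seed_filter(g, config)
        assert not ok and "distinct" in reason

    def test_too_few_members_rejected(self, config, gene_factory):
        g = self.group(config, gene_factory, ["PF14065", "PF04984", "PF06841"])
        ok, reason = seed_filter(g, config)
        assert not ok and "members" in reason


class TestContaminationScreen:
    def scaffold_with_offender(self, config, gene_factory, offset, marker):
        seeds = [
            seed_gene(gene_factory, i, 1 + i * 1500, pfam=p)
            for i, p in enumerate(["PF14065", "PF04984", "PF06841", "PF04865"])
        ]
        (group,) = chain_seed_groups(seeds, 12_000, config)
        last_end = seeds[-1].end
        kw = {"pfams": {marker}} if marker.startswith("PF") else {"cogs": {marker}}
        offender = gene_factory("bad", last_end + offset + 1,
                                last_end + offset + 900, **kw)
        return group, seeds + [offender], offender

    def test_phage_gene_8kb_contaminates(self, config, gene_factory):
        group, genes, offender = self.scaffold_with_offender(
            config, gene_factory, 8000, "PF03864"
        )
        clean, found = contamination_screen(group, genes, config)
        assert not clean and found.gene_id == "bad"

    def test_phage_gene_11kb_is_clean(self, config, gene_factory):
        group, genes, _ = self.scaffold_with_offender(
            config, gene_factory, 11_000, "PF03864"
        )
        assert contamination_screen(group, genes, config) == (True, None)

    def test_member_with_t6ss_cog_contaminates(self, config, gene_factory):
        seeds = [
            seed_gene(gene_factory, i, 1 + i * 1500, pfam=p)
            for i, p in enumerate(["PF14065", "PF04984", "PF06841", "PF04865"])
        ]
        tainted = dataclasses.replace(seeds[1], cogs=frozenset({"COG3523"}))
        genes = [seeds[0], tainted] + seeds[2:]
        (group,) = chain_seed_groups(genes, 12_000, config)
        clean, found = contamination_screen(group, genes, config)
        assert not clean and found.gene_id == tainted.gene_id


class TestExpansion:
    def build(self, gene_factory, n_up, n_down, rna_positions=()):
        genes, pos = [], 1
        for i in range(n_up):
            genes.append(gene_factory(f"u{i}", pos, pos + 500))
            pos += 700
        if "before" in rna_positions:
            genes.append(gene_factory("rna0", pos, pos + 100, coding=False))
            pos += 200
        seed = gene_factory("seed", pos, pos + 900, pfams={"PF14065"})
        genes.append(seed)
        pos += 1100
        for i in range(n_down):
            genes.append(gene_factory(f"d{i}", pos, pos + 500))
            pos += 700
        return genes, seed

    def test_at_scaffold_start_no_error(self, config, gene_factory):
        genes, seed = self.build(gene_factory, 0, 3)
        groups = chain_seed_groups([seed], 12_000, config)
        cand = expand_group(groups[0], genes, 10)
        assert [g.gene_id for g in cand.genes] == ["seed", "d0", "d1", "d2"]

    def test_noncoding_skipped_without_consuming_budget(self, config, gene_factory):
        genes, seed = self.build(gene_factory, 3, 0, rna_positions=("before",))
        groups = chain_seed_groups([seed], 12_000, config)
        cand = expand_group(groups[0], genes, 2)
        # the rRNA between u2 and seed is skipped; 2 coding genes still taken
        assert [g.gene_id for g in cand.genes] == ["u1", "u2", "seed"]

    def test_truncated_when_fewer_available(self, config, gene_factory):
        genes, seed = self.build(gene_factory, 0, 7)
        cand = expand_group(
            chain_seed_groups([seed], 12_000, config)[0], genes, 10
        )
        assert len(cand.genes) == 8  # seed + all 7 downstream


class TestFinalization:
    def candidate(self, gene_factory, n_core, roles, n_flank=6):
        """Scaffold: n_flank plain genes, core genes, n_flank plain genes."""
        genes, pos = [], 1
        for i in range(n_flank):
            genes.append(gene_factory(f"up{i}", pos, pos + 500))
            pos += 700
        core_ids = []
        for i in range(n_core):
            gid = f"core{i}"
            genes.append(gene_factory(gid, pos, pos + 900))
            core_ids.append(gid)
            pos += 1100
        for i in range(n_flank):
            genes.append(gene_factory(f"dn{i}", pos, pos + 500))
            pos += 700
        role_map = {
            gid: frozenset({roles[i % len(roles)]}) for i, gid in enumerate(core_ids)
        }
        cand = CandidateLocus(scaffold_id="s1", genes=genes, seed_groups=[])
        return cand, role_map, genes, core_ids

    def test_ten_cores_with_specific_accepted(self, config, gene_factory):
        cand, roles, genes, _ = self.candidate(
            gene_factory, 10, ["afp1", "afp2", "afp13"]
        )
        locus, reason = finalize_locus(cand, roles, config, genes)
        assert reason is None and locus.n_core_genes == 10

    def test_pyocin_like_rejected_for_missing_specific_core(self, config, gene_factory):
        cand, roles, genes, _ = self.candidate(
            gene_factory, 12, ["afp1", "afp2", "afp5", "afp8"]
        )
        locus, reason = finalize_locus(cand, roles, config, genes)
        assert locus is None and reason == "no eCIS-specific core"

    def test_nine_cores_rejected_on_count(self, config, gene_factory):
        cand, roles, genes, _ = self.candidate(gene_factory, 9, ["afp16"])
        locus, reason = finalize_locus(cand, roles, config, genes)
        assert locus is None and "core count" in reason

    def test_boundary_is_four_coding_genes_each_side(self, config, gene_factory):
        cand, roles, genes, core_ids = self.candidate(
            gene_factory, 10, ["afp1", "afp13"], n_flank=6
        )
        locus, _ = finalize_locus(cand, roles, config, genes)
        assert locus.boundary == ("up2", "dn3")
        assert locus.member_gene_ids[0] == "up2"
        assert locus.member_gene_ids[-1] == "dn3"
        assert len(locus.member_gene_ids) == 4 + 10 + 4

    def test_multiplicity_vs_distinct_switch(self, config, gene_factory):
        cand, roles, genes, _ = self.candidate(
            gene_factory, 10, ["afp1", "afp13"]  # 10 genes, 2 distinct roles
        )
        locus, _ = finalize_locus(cand, roles, config, genes)
        assert locus is not None  # multiplicity counting (default)
        strict = dataclasses.replace(config, count_core_roles_distinct=True)
        locus2, reason = finalize_locus(cand, roles, strict, genes)
        assert locus2 is None and "core count" in reason


def mirror_genome(genes):
    """Reverse a genome's scaffolds: coordinates mirrored, strands flipped."""
    length = {}
    for g in genes:
        length[g.scaffold_id] = max(length.get(g.scaffold_id, 0), g.end + 1000)
    return [
        dataclasses.replace(
            g,
            start=length[g.scaffold_id] - g.end + 1,
            end=length[g.scaffold_id] - g.start + 1,
            strand="-" if g.strand == "+" else "+",
        )
        for g in genes
    ]


class TestDetectEndToEnd:
    def test_valid_plant_recovered_with_all_cores(self, config):
        genes, hits, manifest = make_genome(11, [PlantSpec(kind="ecis_valid")], 30)
        (locus,) = detect_loci(genes, hits, config)
        truth = manifest.scaffolds[0]
        assert set(truth.core_gene_ids) <= set(locus.member_gene_ids)
        assert locus.n_core_genes >= config.thresholds.min_core_genes

    @pytest.mark.parametrize(
        "kind", ["ecis_no_specific_core", "ecis_undersized", "phage_decoy",
                 "t6ss_decoy", "empty"]
    )
    def test_decoys_yield_no_loci(self, config, kind):
        genes, hits, _ = make_genome(12, [PlantSpec(kind=kind)], 30)
        assert detect_loci(genes, hits, config) == []

    def test_two_distant_operons_on_one_scaffold(self, config):
        genes, hits, _ = make_genome(13, [PlantSpec(kind="ecis_valid")], 20)
        scaffold = genes[0].scaffold_id
        offset = max(g.end for g in genes) + 200_000
        shifted = [
            dataclasses.replace(
                g, gene_id=g.gene_id + "_b", scaffold_id=scaffold,
                start=g.start + offset, end=g.end + offset,
            )
            for g in genes
        ]
        hits2 = hits + [
            dataclasses.replace(h, gene_id=h.gene_id + "_b") for h in hits
        ]
        loci = detect_loci(genes + shifted, hits2, config)
        assert len(loci) == 2

    def test_structural_soundness_of_emitted_loci(self, config):
        genes, hits, _ = make_genome(14, standard_plant_mixture(), 60)
        gene_map = {g.gene_id: g for g in genes}
        for locus in detect_loci(genes, hits, config):
            members = [gene_map[g] for g in locus.member_gene_ids]
            assert len({g.scaffold_id for g in members}) == 1
            starts = [g.start for g in members]
            assert starts == sorted(starts)
            assert locus.n_core_genes >= config.thresholds.min_core_genes
            assert locus.roles_present & config.ecis_specific_cores
            assert locus.boundary == (
                locus.member_gene_ids[0], locus.member_gene_ids[-1]
            )

    def test_coordinate_reversal_invariance(self, config):
        genes, hits, _ = make_genome(15, standard_plant_mixture(), 40)
        fwd = detect_loci(genes, hits, config)
        rev = detect_loci(mirror_genome(genes), hits, config)
        assert len(fwd) == len(rev)
        fwd_sets = {frozenset(l.member_gene_ids) for l in fwd}
        rev_sets = {frozenset(l.member_gene_ids) for l in rev}
        assert fwd_sets == rev_sets

    def test_lowering_min_core_genes_is_monotone(self, config):
        genes, hits, _ = make_genome(16, standard_plant_mixture(), 40)
        strict_ids = {l.locus_id for l in detect_loci(genes, hits, config)}
        lax = config.with_thresholds(min_core_genes=5)
        lax_ids = {l.locus_id for l in detect_loci(genes, hits, lax)}
        assert strict_ids <= lax_ids

    def test_report_tallies_are_consistent(self, config):
        genes, hits, _ = make_genome(17, standard_plant_mixture(), 60)
        loci, rep = detect_loci_report(genes, hits, config)
        assert rep.n_loci == len(loci)
        assert (
            rep.n_candidates_merged
            == rep.n_loci + rep.rejected_core_count + rep.rejected_no_specific_core
        )
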