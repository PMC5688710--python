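"""Gene-region priority classification, CGI bands, enhancers, manifest."""

import numpy as np
import pytest

from probemap import (
    CgiIndex,
    EnhancerIndex,
    GeneModel,
    GeneRegionIndex,
    assemble_manifest,
    classify_cgi_context,
    classify_gene_region,
    flag_enhancer,
    load_gene_models,
    probes_per_gene,
    read_manifest,
    write_manifest,
)
from probemap.annotation import (
    BODY, FIRST_EXON, IGR, REGION_PRIORITY, TSS200, TSS1500, UTR3, UTR5,
    GeneModelError, ManifestRow, ProbeAnnotation,
)
from probemap.bisulfite_align import MappingResult
from probemap.mismatch import MismatchReport, TargetSiteClass

# ---------------------------------------------------------------------------
# independent oracle: enumerate every class a site can take for a transcript
# straight from the band/interval definitions, then take max priority


def oracle_classes(pos0, t: GeneModel):
    out = set()
    tss = t.tx_start if t.strand == "+" else t.tx_end - 1
    upstream = tss - pos0 if t.strand == "+" else pos0 - tss
    if 1 <= upstream <= 200:
        out.add(TSS200)
    if 200 < upstream <= 1500:
        out.add(TSS1500)
    if t.tx_start <= pos0 < t.tx_end:
        out.add(BODY)
        first = t.exons[0] if t.strand == "+" else t.exons[-1]
        if first[0] <= pos0 < first[1]:
            out.add(FIRST_EXON)
        exonic = any(s <= pos0 < e for s, e in t.exons)
        if exonic and t.cds_start < t.cds_end:
            before_cds = pos0 < t.cds_start
            after_cds = pos0 >= t.cds_end
            if (t.strand == "+" and before_cds) or (t.strand == "-" and after_cds):
                out.add(UTR5)
            if (t.strand == "+" and after_cds) or (t.strand == "-" and before_cds):
                out.add(UTR3)
    return out


def oracle_region(pos0, transcripts):
    classes = set().union(*(oracle_classes(pos0, t) for t in transcripts)) or {IGR}
    return min(classes, key=REGION_PRIORITY.index)


def _transcript(strand="+", tx=(3000, 6000), cds=(3500, 5500),
                exons=((3000, 3800), (4200, 4800), (5200, 6000)),
                name="NM_1", gene="GeneA", chrom="chr1"):
    return GeneModel(
        transcript_id=name, gene_name=gene, chrom=chrom, strand=strand,
        tx_start=tx[0], tx_end=tx[1], cds_start=cds[0], cds_end=cds[1],
        exon_starts=[s for s, _ in exons], exon_ends=[e for _, e in exons],
    )


class TestLoadGeneModels:
    def _write(self, tmp_path, lines):
        path = tmp_path / "genes.genePred"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_plus_and_minus_tss(self, tmp_path):
        path = self._write(tmp_path, [
            "NM_1\tchr1\t+\t100\t900\t200\t800\t2\t100,500,\t300,900,\t0\tGeneA",
            "NM_2\tchr1\t-\t100\t900\t200\t800\t2\t100,500,\t300,900,\t0\tGeneB",
        ])
        plus, minus = load_gene_models(path)
        assert plus.tss == 100
        assert minus.tss == 899

    def test_leading_bin_column_accepted(self, tmp_path):
        path = self._write(tmp_path, [
            "585\tNM_1\tchr1\t+\t100\t900\t200\t800\t2\t100,500,\t300,900,\t0\tGeneA",
        ])
        (model,) = load_gene_models(path)
        assert model.transcript_id == "NM_1" and model.gene_name == "GeneA"

    def test_exon_list_mismatch_is_error(self, tmp_path):
        path = self._write(tmp_path, [
            "NM_BAD\tchr1\t+\t100\t900\t200\t800\t2\t100,500,\t300,\t0\tGeneA",
        ])
        with pytest.raises(GeneModelError, match="NM_BAD"):
            load_gene_models(path)


class TestClassifyGeneRegion:
    def test_priority_across_transcripts(self):
        # site in TSS200 of A and body of B resolves to TSS200
        a = _transcript(tx=(3000, 6000), name="NM_A", gene="GeneA")
        b = _transcript(tx=(2000, 5000), cds=(2100, 4900),
                        exons=((2000, 2500), (2600, 5000)), name="NM_B", gene="GeneB")
        site_mapinfo = 2951  # 0-based 2950: 50 bp upstream of A's TSS, inside B
        region, names = classify_gene_region(("chr1", site_mapinfo), [a, b])
        assert region == TSS200
        assert names == ["GeneA"]

    def test_beyond_1500_upstream_is_igr(self):
        t = _transcript()
        region, names = classify_gene_region(("chr1", 3000 - 1700 + 1), [t])
        assert region == IGR and names == []

    def test_intron_is_body(self):
        t = _transcript()
        region, _ = classify_gene_region(("chr1", 4001), [t])  # 0-based 4000: intron 1
        assert region == BODY

    def test_noncoding_transcript_has_no_utr(self):
        t = _transcript(cds=(3000, 3000))
        # 0-based 3500 is exonic and before the (absent) CDS
        region, _ = classify_gene_region(("chr1", 3501), [t])
        assert region == FIRST_EXON

    def test_matches_exhaustive_oracle_on_grid(self):
        """Priority resolution equals compute-all-classes-then-max-priority
        over a randomized grid of (site, transcript-set) cases."""
        rng = np.random.default_rng(42)
        n_cases = 0
        for _ in range(60):
            transcripts = []
            for k in range(int(rng.integers(1, 4))):
                tx_start = int(rng.integers(1600, 6000))
                tx_len = int(rng.integers(600, 4000))
                n_ex = int(rng.integers(1, 4))
                cuts = np.sort(rng.choice(np.arange(1, tx_len), size=2 * n_ex - 2,
                                          replace=False))
                bounds = [0, *cuts.tolist(), tx_len]
                exons = [(tx_start + bounds[i], tx_start + bounds[i + 1])
                         for i in range(0, 2 * n_ex - 1, 2)]
                if rng.random() < 0.8:
                    cds_start = int(rng.integers(tx_start, tx_start + tx_len))
                    cds_end = int(rng.integers(cds_start, tx_start + tx_len))
                else:
                    cds_start = cds_end = tx_start
                transcripts.append(GeneModel(
                    transcript_id=f"NM_{k}", gene_name=f"G{k}", chrom="chr1",
                    strand="+" if rng.random() < 0.5 else "-",
                    tx_start=tx_start, tx_end=tx_start + tx_len,
                    cds_start=cds_start, cds_end=cds_end,
                    exon_starts=[s for s, _ in exons],
                    exon_ends=[e for _, e in exons],
                ))
            index = GeneRegionIndex(transcripts)
            for pos0 in rng.integers(0, 12000, size=200):
                pos0 = int(pos0)
                region, _ = index.classify("chr1", pos0 + 1)
                assert region == oracle_region(pos0, transcripts)
                n_cases += 1
        assert n_cases == 12000

    def test_classes_partition_sites(self):
        """Every site gets exactly one class; class counts sum to sites."""
        t = _transcript()
        index = GeneRegionIndex([t])
        counts = {}
        for pos0 in range(0, 8000, 7):
            region, _ = index.classify("chr1", pos0 + 1)
            counts[region] = counts.get(region, 0) + 1
        assert sum(counts.values()) == len(range(0, 8000, 7))
        assert set(counts) <= set(REGION_PRIORITY)


class TestCgiContext:
    ISLANDS = [("chr1", 10_000, 10_500)]

    @pytest.mark.parametrize(
        "pos0, expected",
        [
            (10_000, "Island"), (10_250, "Island"), (10_499, "Island"),
            (10_500 - 1 + 1500, "Shore"),   # 1500 bp past the end
            (10_000 - 1500, "Shore"),        # 1500 bp before the start
            (10_500 - 1 + 3000, "Shelf"),
            (10_500 - 1 + 5000, "OpenSea"),
            (10_000 - 2000, "Shore"),
            (10_000 - 2001, "Shelf"),
        ],
    )
    def test_distance_bands(self, pos0, expected):
        assert classify_cgi_context(("chr1", pos0 + 1), self.ISLANDS) == expected

    def test_no_islands_is_open_sea(self):
        assert classify_cgi_context(("chr2", 5000), self.ISLANDS) == "OpenSea"

    def test_bands_are_exclusive_and_exhaustive(self):
        index = CgiIndex(self.ISLANDS)
        seen = set()
        for pos0 in range(5000, 16000, 13):
            seen.add(index.classify("chr1", pos0 + 1))
        assert seen == {"Island", "Shore", "Shelf", "OpenSea"}


class TestEnhancerFlag:
    BED = [("chr1", 1000, 1200)]

    def test_inside(self):
        assert flag_enhancer(("chr1", 1001), self.BED)  # 0-based 1000

    def test_half_open_end(self):
        assert flag_enhancer(("chr1", 1200), self.BED)        # 0-based 1199: last base
        assert not flag_enhancer(("chr1", 1201), self.BED)    # 0-based 1200: past end

    def test_empty_bed(self):
        assert not flag_enhancer(("chr1", 1100), [])

    def test_probe_span_mode(self):
        index = EnhancerIndex(self.BED)
        assert flag_enhancer(("chr1", 990), index, span=(990, 1039))
        assert not flag_enhancer(("chr1", 990), index, span=(950, 999))


def _unique(probe_id, chrom, mapinfo):
    return MappingResult(probe_id=probe_id, status="unique_best", n_best=1,
                         chrom=chrom, mapinfo=mapinfo, strand="+")


def _row_inputs(probe_ids_coords):
    mapping = [_unique(p, c, m) for p, c, m in probe_ids_coords]
    mm = {p: MismatchReport(p, [], 0, False) for p, _, _ in probe_ids_coords}
    ann = {p: ProbeAnnotation("Body", ["GeneA"], "OpenSea", False)
           for p, _, _ in probe_ids_coords}
    ts = {p: TargetSiteClass("CG", "CpG") for p, _, _ in probe_ids_coords}
    dt = {p: "II" for p, _, _ in probe_ids_coords}
    return mapping, mm, ann, dt, ts


class TestManifest:
    def test_rows_sorted_and_complete(self):
        mapping, mm, ann, dt, ts = _row_inputs(
            [("cg2", "chr2", 10), ("cg1", "chr1", 500), ("cg3", "chr1", 20)])
        rows = assemble_manifest(mapping, mm, ann, dt, ts)
        assert [(r.chrom, r.mapinfo) for r in rows] == [
            ("chr1", 20), ("chr1", 500), ("chr2", 10)]

    def test_ambiguous_probe_absent(self):
        mapping, mm, ann, dt, ts = _row_inputs([("cg1", "chr1", 500)])
        mapping.append(MappingResult(probe_id="cgAMB", status="ambiguous", n_best=2))
        rows = assemble_manifest(mapping, mm, ann, dt, ts)
        assert [r.probe_id for r in rows] == ["cg1"]

    def test_annotation_without_mapping_is_error(self):
        mapping, mm, ann, dt, ts = _row_inputs([("cg1", "chr1", 500)])
        ann["cgGHOST"] = ProbeAnnotation("Body", [], "OpenSea", False)
        with pytest.raises(ValueError, match="cgGHOST"):
            assemble_manifest(mapping, mm, ann, dt, ts)

    def test_tsv_round_trip(self, tmp_path):
        mapping, mm, ann, dt, ts = _row_inputs(
            [("cg1", "chr1", 500), ("cg2", "chr2", 10)])
        rows = assemble_manifest(mapping, mm, ann, dt, ts,
                                 validation={"cg1": True, "cg2": False})
        path = tmp_path / "manifest.tsv"
        write_manifest(rows, path)
        assert read_manifest(path) == rows

    def test_validation_na_when_absent(self, tmp_path):
        mapping, mm, ann, dt, ts = _row_inputs([("cg1", "chr1", 500)])
        rows = assemble_manifest(mapping, mm, ann, dt, ts)
        path = tmp_path / "manifest.tsv"
        write_manifest(rows, path)
        assert "NA" in path.read_text()
        assert read_manifest(path)[0].validation_0_01 is None


class TestProbesPerGene:
    def _row(self, probe_id, genes):
        return ManifestRow(probe_id=probe_id, chrom="chr1", mapinfo=1, strand="+",
                           design_type="II", gene_names=genes, gene_region="Body",
                           cgi_context="OpenSea", fantom5_enhancer=False,
                           target_site="CG", mismatches_pos1_5=False)

    def test_counts(self):
        rows = [self._row("cg1", "GeneX"), self._row("cg2", "GeneX"),
                self._row("cg3", "GeneX"), self._row("cg4", "GeneY")]
        counts, _ = probes_per_gene(rows)
        assert counts == {"GeneX": 3, "GeneY": 1}

    def test_probe_counts_once_per_gene(self):
        counts, _ = probes_per_gene([self._row("cg1", "GeneX;GeneY")])
        assert counts == {"GeneX": 1, "GeneY": 1}

    def test_empty(self):
        assert probes_per_gene([]) == ({}, ([], []))
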