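"""Synthetic-data generator: host genome, proviral insertions, paired reads,
truth alignments and annotation tracks.

The generator emulates the data a host-aligned WGS experiment produces around
viral integrations: a random host chromosome, full- or partial-provirus
insertions at known loci (clean splice, no target-site duplication by
default), 2 x 150 bp paired-end reads with substitution errors and a normal
insert-size distribution, and a truth alignment in host coordinates in which
junction-spanning reads carry soft-clips and fully-viral reads are unmapped
with a mapped host-anchored mate — exactly the populations the candidate
extraction stage consumes.  Every output is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from virin.io_formats import FastaRecord, GenomicInterval, ReadRecord
from virin.viral_search import revcomp

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 0
    host_length: int = 200_000
    gc: float = 0.41  # human-like GC content
    n_insertions: int = 5
    virus_length: int = 9_500  # HERV-K provirus scale
    coverage: float = 30.0
    read_len: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    error_rate: float = 0.005
    fraction_partial: float = 0.4
    min_partial_len: int = 500
    min_spacing: int = 2_000
    edge_margin: int = 1_000
    host_chrom: str = "chr1"

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.read_len < 50:
            raise ValueError("read_len must be >= 50")
        if self.host_length < 10 * self.read_len:
            raise ValueError("host_length must be >= 10 * read_len")


@dataclass
class IntegrationTruth:
    insertion_id: str
    host_chrom: str
    left_junction: int  # 1-based last host base before the virus
    right_junction: int  # 1-based first host base after the virus
    virus_id: str
    virus_start: int  # 1-based on the viral genome
    virus_end: int
    strand: str
    full_length: bool


@dataclass
class _Segment:
    kind: str  # {host, virus}
    aug_start: int  # 0-based start on the augmented genome
    length: int
    host_start: int = 0  # 0-based host offset (host segments)


@dataclass
class SimulatedSample:
    config: SimulationConfig
    host: FastaRecord
    virus: FastaRecord
    augmented: str
    segments: list[_Segment]
    truth: list[IntegrationTruth]
    reads: list[tuple[str, str, str]] = field(default_factory=list)  # R1 FASTQ
    reads2: list[tuple[str, str, str]] = field(default_factory=list)  # R2 FASTQ
    alignment: list[ReadRecord] = field(default_factory=list)

    @property
    def truth_junctions(self) -> list[int]:
        out = []
        for t in self.truth:
            out.extend([t.left_junction, t.right_junction])
        return sorted(out)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def simulate_host(config: SimulationConfig, rng: np.random.Generator | None = None) -> FastaRecord:
    """Random host chromosome: i.i.d. bases at the configured GC content."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    return FastaRecord(config.host_chrom, "simulated host", _random_seq(rng, config.host_length, config.gc))


def simulate_virus(
    config: SimulationConfig, rng: np.random.Generator | None = None, virus_id: str = "HERVK_sim"
) -> FastaRecord:
    """Random proviral genome at ~9.5 kb by default (synthetic stand-in)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    return FastaRecord(virus_id, "simulated provirus", _random_seq(rng, config.virus_length, 0.45))


def plant_integrations(
    host: FastaRecord,
    virus: FastaRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, list[_Segment], list[IntegrationTruth]]:
    """Splice full/partial proviruses into the host at spaced random loci.

    Sites are rejection-sampled to lie >= edge_margin from the chromosome ends
    and >= min_spacing apart.  Truth junctions are recorded in pre-insertion
    host coordinates: left = last host base before the virus (1-based),
    right = left + 1.
    """
    n = config.n_insertions
    hlen = len(host.seq)
    lo, hi = config.edge_margin, hlen - config.edge_margin
    if n > 0 and (hi - lo) < (n - 1) * config.min_spacing:
        raise ValueError("host too short for the requested insertions and spacing")
    sites: list[int] = []
    attempts = 0
    while len(sites) < n:
        attempts += 1
        if attempts > 100_000:
            raise ValueError("could not place insertions under spacing constraints")
        p = int(rng.integers(lo, hi))
        if all(abs(p - s) >= config.min_spacing for s in sites):
            sites.append(p)
    sites.sort()

    n_partial = int(round(config.fraction_partial * n))
    partial_flags = [i < n_partial for i in range(n)]
    rng.shuffle(partial_flags)

    vlen = len(virus.seq)
    segments: list[_Segment] = []
    truth: list[IntegrationTruth] = []
    pieces: list[str] = []
    host_cursor = 0
    aug_cursor = 0
    for i, p in enumerate(sites):
        # host block up to and including host base p (1-based) = host[0:p]
        block = host.seq[host_cursor:p]
        if block:
            segments.append(_Segment("host", aug_cursor, len(block), host_start=host_cursor))
            pieces.append(block)
            aug_cursor += len(block)
        if partial_flags[i]:
            span = int(rng.integers(config.min_partial_len, max(config.min_partial_len + 1, vlen)))
            vs = int(rng.integers(0, vlen - span + 1))
            ve = vs + span
            full = False
        else:
            vs, ve = 0, vlen
            full = True
        strand = "+" if rng.random() < 0.5 else "-"
        insert = virus.seq[vs:ve] if strand == "+" else revcomp(virus.seq[vs:ve])
        segments.append(_Segment("virus", aug_cursor, len(insert)))
        pieces.append(insert)
        aug_cursor += len(insert)
        truth.append(
            IntegrationTruth(
                insertion_id=f"ins{i + 1}",
                host_chrom=host.id,
                left_junction=p,
                right_junction=p + 1,
                virus_id=virus.id,
                virus_start=vs + 1,
                virus_end=ve,
                strand=strand,
                full_length=full,
            )
        )
        host_cursor = p
    tail = host.seq[host_cursor:]
    if tail:
        segments.append(_Segment("host", aug_cursor, len(tail), host_start=host_cursor))
        pieces.append(tail)
    return "".join(pieces), segments, truth


_QUAL_PHRED = np.array([32, 35, 37, 39, 41])
_QUAL_P = np.array([0.05, 0.10, 0.20, 0.30, 0.35])


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    errs = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in errs:
        alternatives = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = alternatives[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def _qual_string(rng: np.random.Generator, n: int, error_rate: float) -> str:
    # Illumina-like distribution; decorative realism, not coupled per-base to
    # the planted errors (see methods note)
    if error_rate <= 0:
        return chr(40 + 33) * n
    phreds = rng.choice(_QUAL_PHRED, size=n, p=_QUAL_P)
    return "".join(chr(int(q) + 33) for q in phreds)


def simulate_reads(
    sample: SimulatedSample, rng: np.random.Generator
) -> list[tuple[int, int, bool]]:
    """Draw paired-end fragments and fill sample.reads/reads2.

    Returns per-pair provenance: (fragment start, fragment end, r1_is_forward)
    in augmented 0-based coordinates.  Fragment lengths are
    Normal(insert_mean, insert_sd) truncated below at 2 x read_len; starts are
    uniform; substitution errors at error_rate; FR orientation.
    """
    cfg = sample.config
    genome = sample.augmented
    glen = len(genome)
    n_pairs = int(round(cfg.coverage * glen / (2 * cfg.read_len)))
    provenance: list[tuple[int, int, bool]] = []
    rl = cfg.read_len
    for i in range(n_pairs):
        frag = max(2 * rl, int(round(rng.normal(cfg.insert_mean, cfg.insert_sd))))
        frag = min(frag, glen)
        start = int(rng.integers(0, glen - frag + 1))
        end = start + frag
        fwd = genome[start : start + rl]
        rev = revcomp(genome[end - rl : end])
        r1_is_forward = bool(rng.random() < 0.5)
        name = f"sim{i + 1}"
        s1 = _mutate(fwd if r1_is_forward else rev, rng, cfg.error_rate)
        s2 = _mutate(rev if r1_is_forward else fwd, rng, cfg.error_rate)
        q1 = _qual_string(rng, rl, cfg.error_rate)
        q2 = _qual_string(rng, rl, cfg.error_rate)
        sample.reads.append((name, s1, q1))
        sample.reads2.append((name, s2, q2))
        provenance.append((start, end, r1_is_forward))
    return provenance


def _locate(segments: list[_Segment], s: int, e: int) -> list[tuple[_Segment, int, int]]:
    """Segments overlapped by augmented interval [s, e), with local offsets."""
    out = []
    for seg in segments:
        a, b = seg.aug_start, seg.aug_start + seg.length
        if b <= s or a >= e:
            continue
        out.append((seg, max(s, a) - a, min(e, b) - a))
    return out


def emit_truth_alignment(
    sample: SimulatedSample, provenance: list[tuple[int, int, bool]]
) -> list[ReadRecord]:
    """Truth SAM records against the host-only reference.

    Reads wholly in host segments are mapped full-match; junction-spanning
    reads are mapped on the host side with the viral side soft-clipped;
    fully-viral reads are unmapped (flag 0x4) and, when their mate is
    host-anchored, carry the mate's coordinates — reproducing the
    ``-f 4 -F 264`` candidate population.
    """
    cfg = sample.config
    rl = cfg.read_len
    records: list[ReadRecord] = []
    chrom = sample.host.id
    for i, (start, end, r1_is_forward) in enumerate(provenance):
        name = f"sim{i + 1}"
        fwd_iv = (start, start + rl)  # forward-oriented read interval
        rev_iv = (end - rl, end)  # reverse-oriented read interval
        mates = []
        for mate_idx, (iv, is_reverse) in enumerate(
            [(fwd_iv, False), (rev_iv, True)] if r1_is_forward else [(rev_iv, True), (fwd_iv, False)]
        ):
            raw = sample.reads[i][1] if mate_idx == 0 else sample.reads2[i][1]
            qual = sample.reads[i][2] if mate_idx == 0 else sample.reads2[i][2]
            # forward-genome orientation of the (errored) read
            fseq = revcomp(raw) if is_reverse else raw
            fqual = qual[::-1] if is_reverse else qual
            parts = _locate(sample.segments, iv[0], iv[1])
            host_parts = [(seg, a, b) for seg, a, b in parts if seg.kind == "host"]
            if not host_parts:
                mates.append(
                    dict(mapped=False, reverse=is_reverse, raw=raw, rawq=qual,
                         fseq=fseq, fqual=fqual, pos=0, cigar=[], end=0)
                )
                continue
            # at most one host part per read (viral inserts exceed read length)
            seg, a, b = host_parts[0]
            host_pos = seg.host_start + a + 1  # 1-based
            host_len = b - a
            clip = rl - host_len
            aug_host_start = seg.aug_start + a
            if clip == 0:
                cigar = [("M", rl)]
            elif aug_host_start > iv[0]:
                cigar = [("S", clip), ("M", host_len)]  # virus | host
            else:
                cigar = [("M", host_len), ("S", clip)]  # host | virus
            mates.append(
                dict(mapped=True, reverse=is_reverse, raw=raw, rawq=qual,
                     fseq=fseq, fqual=fqual, pos=host_pos, cigar=cigar,
                     end=host_pos + host_len - 1)
            )
        for mate_idx, (me, other) in enumerate([(mates[0], mates[1]), (mates[1], mates[0])]):
            flag = 0x1 | (0x40 if mate_idx == 0 else 0x80)
            if me["mapped"] and other["mapped"]:
                flag |= 0x2
            if not me["mapped"]:
                flag |= 0x4
            if not other["mapped"]:
                flag |= 0x8
            if me["mapped"] and me["reverse"]:
                flag |= 0x10
            if other["mapped"] and other["reverse"]:
                flag |= 0x20
            if me["mapped"]:
                rname, pos, mapq, cigar = chrom, me["pos"], 60, me["cigar"]
                seq, qual = me["fseq"], me["fqual"]
            else:
                seq, qual = me["raw"], me["rawq"]
                mapq, cigar = 0, []
                if other["mapped"]:
                    rname, pos = chrom, other["pos"]  # placed at the mate
                else:
                    rname, pos = "*", 0
            if other["mapped"]:
                mate_rname, mate_pos = ("=" if rname == chrom else chrom), other["pos"]
            elif me["mapped"]:
                mate_rname, mate_pos = "=", me["pos"]  # unmapped mate placed here
            else:
                mate_rname, mate_pos = "*", 0
            if me["mapped"] and other["mapped"]:
                left = min(me["pos"], other["pos"])
                right = max(me["end"], other["end"])
                tlen = right - left + 1
                if me["pos"] > other["pos"] or (me["pos"] == other["pos"] and mate_idx == 1):
                    tlen = -tlen
            else:
                tlen = 0
            records.append(
                ReadRecord(
                    qname=name, flag=flag, rname=rname, pos=pos, mapq=mapq,
                    cigar=cigar, seq=seq, qual=qual,
                    mate_rname=mate_rname, mate_pos=mate_pos, tlen=tlen,
                )
            )
    return records


@dataclass
class TrackLayout:
    """Explicit placement of synthetic genes, repeats and DNase sites
    (all coordinates 0-based half-open on the host)."""

    genes: list[dict] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)
    dnase: list[tuple[int, int]] = field(default_factory=list)


def emit_tracks(
    layout: TrackLayout, chrom: str
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[str]]:
    """Render a layout as (dnase intervals, repeat intervals, GTF lines).

    Overlapping intervals within the dnase or repeat track are a spec
    conflict and raise ValueError.
    """

    def check_disjoint(ivs: list[tuple[int, int]], label: str) -> None:
        ivs = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping {label} intervals in layout: {(s1, e1)} vs {(s2, e2)}")

    check_disjoint(list(layout.dnase), "dnase")
    check_disjoint([(r["start"], r["end"]) for r in layout.repeats], "repeat")

    dnase = [GenomicInterval(chrom, s, e, name="DHS") for s, e in layout.dnase]
    repeats = [
        GenomicInterval(
            chrom, r["start"], r["end"],
            name=r["repeat_class"], score=float(r.get("score", 0)),
            attrs={"repeat_class": r["repeat_class"]},
        )
        for r in layout.repeats
    ]
    gtf_lines: list[str] = []
    for g in layout.genes:
        attrs = f'gene_id "{g["name"]}"; gene_name "{g["name"]}"; gene_type "{g["gene_type"]}";'
        gtf_lines.append(
            "\t".join(
                [chrom, "sim", "gene", str(g["start"] + 1), str(g["end"]), ".", g["strand"], ".", attrs]
            )
        )
        for s, e in g.get("exons", [(g["start"], g["end"])]):
            gtf_lines.append(
                "\t".join([chrom, "sim", "exon", str(s + 1), str(e), ".", g["strand"], ".", attrs])
            )
        for s, e in g.get("cds", []):
            gtf_lines.append(
                "\t".join([chrom, "sim", "CDS", str(s + 1), str(e), ".", g["strand"], ".", attrs])
            )
    return dnase, repeats, gtf_lines


def layout_for_truth(
    truth: list[IntegrationTruth], host_length: int, promoter_up: int = 2000
) -> tuple[TrackLayout, dict[int, dict]]:
    """A deterministic annotation context for each planted insertion.

    Cycles through promoter / exon / intron / intergenic gene contexts and
    LTR / LINE / none repeat contexts, alternating DNase overlap, and returns
    the expected labels keyed by junction position (both junctions of an
    insertion share one context: they are adjacent host bases).
    """
    layout = TrackLayout()
    expected: dict[int, dict] = {}
    for i, t in enumerate(truth):
        p0 = t.left_junction - 1  # 0-based left-junction base
        ctx = i % 4
        gname = f"G{i + 1}"
        if ctx == 0:  # promoter: TSS 500 bases downstream of the junction
            layout.genes.append(
                dict(name=gname, gene_type="protein_coding", strand="+",
                     start=p0 + 500, end=p0 + 1500,
                     exons=[(p0 + 500, p0 + 1500)], cds=[(p0 + 600, p0 + 1400)])
            )
            region, gene, gtype = "promoter", gname, "protein_coding"
        elif ctx == 1:  # exon (CDS) of a protein-coding gene
            layout.genes.append(
                dict(name=gname, gene_type="protein_coding", strand="+",
                     start=p0 - 400, end=p0 + 400,
                     exons=[(p0 - 400, p0 + 400)], cds=[(p0 - 300, p0 + 300)])
            )
            region, gene, gtype = "exon", gname, "protein_coding"
        elif ctx == 2:  # intron of a lncRNA
            layout.genes.append(
                dict(name=gname, gene_type="lncRNA", strand="-",
                     start=p0 - 400, end=p0 + 400,
                     exons=[(p0 - 400, p0 - 300), (p0 + 300, p0 + 400)])
            )
            region, gene, gtype = "intron", gname, "lncRNA"
        else:
            region, gene, gtype = "intergenic", None, "none"
        if i % 2 == 0:
            layout.dnase.append((p0 - 50, p0 + 50))
            dnase = True
        else:
            dnase = False
        rep = ["LTR", "LINE", "none"][i % 3]
        if rep != "none":
            layout.repeats.append(dict(start=p0 - 60, end=p0 + 60, repeat_class=rep, score=1000))
        labels = dict(region_class=region, gene_name=gene, gene_type=gtype,
                      dnase=dnase, repeat_class=rep)
        expected[t.left_junction] = labels
        expected[t.right_junction] = labels
    return layout, expected


def simulate_sample(config: SimulationConfig) -> tuple[SimulatedSample, list[tuple[int, int, bool]]]:
    """End-to-end simulation: host, virus, insertions, reads, truth alignment."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    host = simulate_host(config, rng)
    virus = simulate_virus(config, np.random.default_rng(config.seed + 1))
    augmented, segments, truth = plant_integrations(host, virus, config, rng)
    sample = SimulatedSample(
        config=config, host=host, virus=virus,
        augmented=augmented, segments=segments, truth=truth,
    )
    provenance = simulate_reads(sample, rng)
    sample.alignment = emit_truth_alignment(sample, provenance)
    return sample, provenance
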