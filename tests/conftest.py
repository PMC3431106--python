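import numpy as np
import pandas as pd
import pytest

from tspsr.annotation import (
    ExpressionStudy,
    Gene,
    GenomeAnnotation,
    ProbeSelectionRegion,
    SampleRecord,
    Transcript,
)


def make_gene(gene_id, chrom, strand, tx_exons, biotypes=None):
    """tx_exons: dict transcript_id -> list of (start, end)."""
    g = Gene(gene_id, chrom, strand)
    for i, (tx_id, exons) in enumerate(tx_exons.items()):
        bt = (biotypes or {}).get(tx_id, "protein_coding")
        g.transcripts[tx_id] = Transcript(tx_id, bt, sorted(exons))
    return g


def make_psr(psr_id, chrom, strand, start, end, reliable=True, class1=True):
    return ProbeSelectionRegion(psr_id, chrom, strand, start, end, reliable, class1)


@pytest.fixture
def two_transcript_gene():
    """Gene with a shared exon and one unique exon per transcript."""
    return GenomeAnnotation(
        [
            make_gene(
                "GA",
                "chr1",
                "+",
                {
                    "GA-T1": [(100, 200), (300, 400)],
                    "GA-T2": [(100, 200), (500, 600)],
                },
            )
        ]
    )


def make_study(matrix, groups, background=0.0, rng=None):
    """Build an ExpressionStudy from a DataFrame and a sample_id->group map."""
    samples = []
    for sid in matrix.columns:
        grp = groups[sid]
        if grp == "PRIMARY":
            samples.append(SampleRecord(sid, grp, bcr_time=12.0, bcr_event=False,
                                        nomogram_prob=0.2))
        else:
            samples.append(SampleRecord(sid, grp))
    return ExpressionStudy(matrix=matrix, samples=samples, background_level=background)


def random_toy_genome(rng, n_genes=20):
    """Random small annotation + PSR set with varied pathology for oracle tests."""
    genes = []
    psrs = []
    cursor = 500
    counter = 0
    chrom = "chrT"
    for gi in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(1, 4))
        n_shared = int(rng.integers(1, 3))
        slots = []
        pos = cursor
        n_unique = [int(rng.integers(0, 3)) for _ in range(n_tx)]
        for _ in range(n_shared + sum(n_unique)):
            ln = int(rng.integers(60, 200))
            slots.append((pos, pos + ln))
            pos += ln + int(rng.integers(100, 600))
        owners = [-1] * n_shared
        for t, k in enumerate(n_unique):
            owners += [t] * k
        order = rng.permutation(len(slots))
        g = Gene(f"TG{gi}", chrom, strand)
        for t in range(n_tx):
            exons = sorted(
                slots[s] for s, o in zip(order, owners) if o in (-1, t)
            )
            g.transcripts[f"TG{gi}-T{t}"] = Transcript(f"TG{gi}-T{t}", "protein_coding", exons)
        genes.append(g)
        # PSRs: inside exons, straddling, and intergenic
        for s, e in {tuple(x) for t in g.transcripts.values() for x in t.exons}:
            for _ in range(int(rng.integers(1, 3))):
                ln = min(int(rng.integers(20, 80)), e - s)
                st = int(rng.integers(s, e - ln + 1))
                counter += 1
                psrs.append(
                    ProbeSelectionRegion(
                        f"TP{counter}", chrom,
                        strand if rng.random() < 0.8 else ("-" if strand == "+" else "+"),
                        st, st + ln,
                        reliable=rng.random() > 0.2,
                        crosshyb_class1=rng.random() > 0.15,
                    )
                )
        counter += 1
        psrs.append(  # likely intronic/intergenic probe
            ProbeSelectionRegion(
                f"TP{counter}", chrom, strand, pos + 10, pos + 50, True, True
            )
        )
        cursor = pos + int(rng.integers(1000, 4000))
    # one same-strand nested pair to exercise the multi-gene filter
    host = Gene("TG_HOST", chrom, "+")
    host.transcripts["TG_HOST-T0"] = Transcript(
        "TG_HOST-T0", "protein_coding", [(cursor, cursor + 100), (cursor + 8000, cursor + 8100)]
    )
    nest = Gene("TG_NEST", chrom, "+")
    nest.transcripts["TG_NEST-T0"] = Transcript(
        "TG_NEST-T0", "protein_coding", [(cursor + 2000, cursor + 2100)]
    )
    nest.transcripts["TG_NEST-T1"] = Transcript(
        "TG_NEST-T1", "protein_coding", [(cursor + 2000, cursor + 2100), (cursor + 3000, cursor + 3100)]
    )
    genes += [host, nest]
    psrs.append(ProbeSelectionRegion("TP_NEST", chrom, "+", cursor + 3010, cursor + 3060, True, True))
    return GenomeAnnotation(genes), psrs
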