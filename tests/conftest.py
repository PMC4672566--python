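"""Shared fixtures: toy VCF/BAM inputs and hand-built panels.

All fixtures are generated programmatically at test time; expected values
are hand-transcribed from the generators below.
"""

from __future__ import annotations

import numpy as np
import pytest

from ldid import ReferencePanel, SnpSite

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##contig=<ID=2,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, samples, records):
    """records: (chrom, pos, id, ref, alt, [genotype strings])."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(samples="\t".join(samples)))
        for chrom, pos, rid, ref, alt, gts in records:
            row = [str(chrom), str(pos), rid, ref, alt, ".", "PASS", ".", "GT"]
            fh.write("\t".join(row + list(gts)) + "\n")


# Hand-transcribed haplotype matrix of the three clean records in toy_vcf,
# row order (S1.A, S1.B, S2.A, S2.B, S3.A, S3.B, S4.A, S4.B):
TOY_VCF_MATRIX = np.array(
    [
        [0, 0, 1],
        [1, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [0, 1, 1],
        [1, 1, 0],
    ],
    dtype=np.uint8,
)


@pytest.fixture
def toy_vcf(tmp_path):
    """4-sample VCF: 3 clean phased SNPs plus one record per discard rule."""
    path = tmp_path / "toy.vcf"
    write_vcf(
        path,
        ["S1", "S2", "S3", "S4"],
        [
            ("1", 100, "rs1", "A", "G", ["0|1", "1|1", "0|0", "0|1"]),
            ("1", 150, "indel", "A", "AT", ["0|0", "0|1", "0|0", "0|0"]),
            ("1", 160, "multi", "A", "C,G", ["0|1", "0|2", "0|0", "0|0"]),
            ("1", 170, "mono", "C", "T", ["0|0", "0|0", "0|0", "0|0"]),
            ("1", 180, "unphased", "A", "C", ["0|1", "0/1", "0|0", "0|0"]),
            ("1", 190, "missing", "A", "C", ["0|1", ".|.", "0|0", "0|0"]),
            ("1", 200, "rs2", "C", "A", ["0|0", "0|1", "1|0", "1|1"]),
            ("2", 50, "rs3", "T", "A", ["1|0", "0|0", "0|1", "1|0"]),
        ],
    )
    return path


@pytest.fixture
def mac_vcf(tmp_path):
    """100-sample VCF (200 haplotypes): alt counts 9 and 10 at two sites."""
    path = tmp_path / "mac.vcf"
    samples = [f"S{i}" for i in range(100)]

    def gts(alt_count):
        out = []
        remaining = alt_count
        for _ in range(100):
            if remaining >= 2:
                out.append("1|1")
                remaining -= 2
            elif remaining == 1:
                out.append("1|0")
                remaining -= 1
            else:
                out.append("0|0")
        return out

    write_vcf(
        path,
        samples,
        [
            ("1", 1000, "mac9", "A", "C", gts(9)),
            ("1", 2000, "mac10", "A", "C", gts(10)),
        ],
    )
    return path


def make_panel(columns, positions, alleles=None, chrom="1"):
    """Build a panel from explicit 0/1 columns at given 1-based positions."""
    columns = np.asarray(columns, dtype=np.uint8)
    if alleles is None:
        alleles = [("A", "C")] * columns.shape[1]
    sites = [
        SnpSite(chrom, int(p), ref, alt)
        for p, (ref, alt) in zip(positions, alleles)
    ]
    return ReferencePanel(sites, columns, population_label="toy")


def random_two_site_panel(rng):
    """A random polymorphic panel of 4-16 haplotypes over two linked sites."""
    n = int(rng.integers(2, 9)) * 2
    while True:
        H = rng.integers(0, 2, size=(n, 2), dtype=np.uint8)
        if 0 < H[:, 0].sum() < n and 0 < H[:, 1].sum() < n:
            break
    sites = [SnpSite("1", 1000, "A", "C"), SnpSite("1", 5000, "G", "T")]
    return ReferencePanel(sites, H)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort (60 x 500 kb segments) shared across tests."""
    from ldid import SimScenario, simulate_cohort

    return simulate_cohort(SimScenario(n_segments=60, seed=2024), n_individuals=2)


# -- engineered alignment fixture -----------------------------------------

#: (pos, ref, alt, reads) where reads are (base, base_quality, mapping_quality)
BAM_SITES = [
    (100, "A", "T", [("A", 40, 60)]),          # emit code 0
    (200, "A", "T", [("T", 40, 60)]),          # emit code 1
    (300, "A", "T", [("A", 40, 60), ("A", 40, 60)]),  # multi-read -> omitted
    (400, "A", "T", [("G", 40, 60)]),          # base matches neither -> discard
    (500, "C", "T", [("C", 40, 60)]),          # transition site (damage-prone)
    (600, "A", "C", [("A", 10, 60)]),          # low base quality -> no coverage
    (700, "A", "C", [("A", 40, 10)]),          # low mapping quality -> no coverage
]


@pytest.fixture(scope="session")
def bam_panel():
    cols = np.array(
        [[0, 0, 1, 1]] * len(BAM_SITES), dtype=np.uint8
    ).T  # every column [0,0,1,1]
    return make_panel(
        cols,
        [p for p, *_ in BAM_SITES],
        [(r, a) for _, r, a, _ in BAM_SITES],
    )


@pytest.fixture(scope="session")
def toy_bam(tmp_path_factory):
    """Coordinate-sorted, indexed BAM realising the BAM_SITES read table."""
    import pysam

    path = tmp_path_factory.mktemp("bam") / "toy.bam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "1", "LN": 1_000_000}],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        serial = 0
        for pos, _ref, _alt, reads in BAM_SITES:
            for base, bq, mq in reads:
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"read{serial}"
                serial += 1
                a.query_sequence = base + "A" * 9
                a.reference_id = 0
                a.reference_start = pos - 1  # site base is the first base
                a.mapping_quality = mq
                a.cigarstring = "10M"
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(bq + 33) * 10
                )
                bam.write(a)
    pysam.index(str(path))
    return path
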