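"""Phased reference haplotype panels.

A reference panel is a matrix of phased haplotypes over filtered biallelic
SNPs. It supplies the allele frequencies f(A) and haplotype frequencies
f(AB) that drive the identity test. Panels are built from a phased
multi-sample VCF, optionally restricted to a mappability mask, and filtered
to sites that are polymorphic in the chosen sample subset with a minimum
minor allele count (default 10) so that marginal frequencies are bounded
away from 0 and 1.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zipfile
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))

PANEL_FORMAT_VERSION = 1


class PanelError(Exception):
    """Raised for malformed panels or panel archives."""


@dataclass(frozen=True)
class SnpSite:
    """A biallelic SNP with 1-based position (VCF convention)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    site_id: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


def is_transversion_site(site: SnpSite) -> bool:
    """True iff the ref/alt pair is a transversion (purine<->pyrimidine).

    Transition pairs {A,G} and {C,T} return False. Transversion-only mode
    sidesteps the C->T / G->A substitutions typical of post-mortem
    deamination damage in ancient DNA.
    """
    return frozenset((site.ref_allele, site.alt_allele)) not in _TRANSITIONS


class MappabilityMask:
    """Per-chromosome sets of 0-based half-open intervals of unique sequence.

    Intended to encode a short-read mappability track (e.g. regions where
    every overlapping 35-mer is unique); a SNP is retained iff its single
    base position falls inside an interval.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            for (s0, e0), (s1, _e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping mask intervals on {chrom}: "
                        f"({s0},{e0}) and ({s1},{_e1})"
                    )
            self._starts[chrom] = np.array([s for s, _ in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in ivs], dtype=np.int64)

    @classmethod
    def from_bed(cls, path) -> "MappabilityMask":
        """Read a (>=3-column) BED file: chrom, start (0-based), end."""
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                intervals.setdefault(chrom, []).append((start, end))
        return cls(intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]


class ReferencePanel:
    """Phased 0/1 haplotype matrix over ordered biallelic SNPs.

    Parameters
    ----------
    sites:
        SNPs sorted by (chrom, pos), strictly increasing within chromosome.
    haplotypes:
        uint8 matrix, shape (n_haplotypes, n_sites); 0 = ref allele,
        1 = alt allele. Every column must contain both codes and satisfy
        the minor-allele-count threshold recorded in ``metadata``.
    population_label:
        Free-text label of the population the haplotypes represent.
    metadata:
        Provenance (filter settings, source file, sample names, ...).
    """

    def __init__(
        self,
        sites: list[SnpSite],
        haplotypes: np.ndarray,
        population_label: str = "",
        metadata: dict | None = None,
    ):
        haplotypes = np.ascontiguousarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2:
            raise PanelError("haplotypes must be a 2-D matrix")
        if haplotypes.shape[1] != len(sites):
            raise PanelError(
                f"haplotype matrix has {haplotypes.shape[1]} columns "
                f"for {len(sites)} sites"
            )
        if haplotypes.shape[0] < 2:
            raise PanelError("a panel needs at least 2 haplotypes")
        if haplotypes.size and not np.isin(haplotypes, (0, 1)).all():
            raise PanelError("haplotype codes must be 0 or 1")
        prev = None
        for s in sites:
            if prev is not None and s.chrom == prev.chrom and s.pos <= prev.pos:
                raise PanelError(
                    f"sites out of order at {s.chrom}:{s.pos} (after {prev.pos})"
                )
            prev = s
        alt = haplotypes.sum(axis=0)
        if ((alt == 0) | (alt == haplotypes.shape[0])).any():
            raise PanelError("monomorphic column in panel")
        self.sites = list(sites)
        self.haplotypes = haplotypes
        self.population_label = population_label
        self.metadata = dict(metadata or {})
        self._pos = np.array([s.pos for s in sites], dtype=np.int64)
        self._chroms = [s.chrom for s in sites]
        self._alt_counts = alt.astype(np.int64)
        self._fingerprint: str | None = None

    # -- basic geometry ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def positions(self) -> np.ndarray:
        """1-based positions, aligned with ``sites``."""
        return self._pos

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome name per site, aligned with ``sites``."""
        return self._chroms

    def chrom_ranges(self) -> dict[str, tuple[int, int]]:
        """Half-open [start, stop) site-index range of each chromosome."""
        ranges: dict[str, tuple[int, int]] = {}
        start = 0
        n = len(self._chroms)
        for i in range(1, n + 1):
            if i == n or self._chroms[i] != self._chroms[start]:
                ranges[self._chroms[start]] = (start, i)
                start = i
        return ranges

    # -- frequencies -------------------------------------------------------

    def allele_count(self, site_index: int, allele_code: int) -> int:
        """Count of ``allele_code`` (0 or 1) among panel haplotypes."""
        self._check_index(site_index)
        c1 = int(self._alt_counts[site_index])
        return c1 if allele_code == 1 else self.n_haplotypes - c1

    def allele_freq(self, site_index: int, allele_code: int) -> float:
        """Empirical allele frequency; strictly in (0, 1) by construction."""
        return self.allele_count(site_index, allele_code) / self.n_haplotypes

    def haplotype_count(
        self, site_i: int, allele_a: int, site_j: int, allele_b: int
    ) -> int:
        """Number of panel haplotypes carrying allele_a at i and allele_b at j."""
        self._check_index(site_i)
        self._check_index(site_j)
        if site_i == site_j:
            raise ValueError("haplotype frequency requires two distinct sites")
        col_i = self.haplotypes[:, site_i]
        col_j = self.haplotypes[:, site_j]
        return int(np.count_nonzero((col_i == allele_a) & (col_j == allele_b)))

    def haplotype_freq(
        self, site_i: int, allele_a: int, site_j: int, allele_b: int
    ) -> float:
        """Empirical two-site haplotype frequency f(AB); may be exactly 0."""
        return (
            self.haplotype_count(site_i, allele_a, site_j, allele_b)
            / self.n_haplotypes
        )

    def _check_index(self, i: int) -> None:
        if not 0 <= i < self.n_sites:
            raise IndexError(f"site index {i} out of range [0, {self.n_sites})")

    # -- identity ----------------------------------------------------------

    def fingerprint(self) -> str:
        """SHA-256 over sites and haplotype matrix; ties observations to panels."""
        if self._fingerprint is None:
            h = hashlib.sha256()
            for s in self.sites:
                h.update(
                    f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\n".encode()
                )
            h.update(np.packbits(self.haplotypes, axis=None).tobytes())
            self._fingerprint = h.hexdigest()
        return self._fingerprint

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReferencePanel)
            and self.sites == other.sites
            and np.array_equal(self.haplotypes, other.haplotypes)
            and self.population_label == other.population_label
        )


@dataclass
class BuildStats:
    """Per-rule counters from a panel build, for audit logging."""

    records: int = 0
    non_snp: int = 0
    unphased: int = 0
    missing_genotype: int = 0
    monomorphic: int = 0
    below_mac: int = 0
    outside_mask: int = 0
    retained: int = 0


def build_panel(
    vcf_source,
    sample_subset: list[str] | None = None,
    min_minor_count: int = 10,
    mask: MappabilityMask | None = None,
    population_label: str = "",
    return_stats: bool = False,
):
    """Build a :class:`ReferencePanel` from a phased multi-sample VCF.

    Retains only biallelic single-base substitutions that are polymorphic
    within ``sample_subset`` with minor allele count >= ``min_minor_count``
    and (if ``mask`` is given) whose position lies inside a mask interval.
    Records with unphased or missing genotypes in the subset are dropped and
    counted. Haplotype rows are ordered (sample order, haplotype A then B).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source), gts012=False)
    if sample_subset is None:
        sample_subset = list(vcf.samples)
    else:
        missing = [s for s in sample_subset if s not in vcf.samples]
        if missing:
            raise PanelError(f"sample(s) not in VCF: {', '.join(missing)}")
    col_of = {s: i for i, s in enumerate(vcf.samples)}
    cols = [col_of[s] for s in sample_subset]
    n_hap = 2 * len(sample_subset)

    stats = BuildStats()
    sites: list[SnpSite] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        stats.records += 1
        if (
            len(var.ALT) != 1
            or var.REF not in _BASES
            or var.ALT[0] not in _BASES
        ):
            stats.non_snp += 1
            continue
        if mask is not None and not mask.contains(var.CHROM, var.POS - 1):
            stats.outside_mask += 1
            continue
        gts = var.genotypes  # per sample: [allele0, allele1, phased]
        hap = np.empty(n_hap, dtype=np.int16)
        ok = True
        unphased = False
        for k, c in enumerate(cols):
            a0, a1, phased = gts[c][0], gts[c][1], gts[c][2]
            if a0 < 0 or a1 < 0:
                ok = False
                break
            if not phased and a0 != a1:  # homozygotes are trivially phased
                unphased = True
                break
            hap[2 * k] = a0
            hap[2 * k + 1] = a1
        if unphased:
            stats.unphased += 1
            continue
        if not ok:
            stats.missing_genotype += 1
            continue
        alt = int(hap.sum())
        if alt == 0 or alt == n_hap:
            stats.monomorphic += 1
            continue
        if min(alt, n_hap - alt) < min_minor_count:
            stats.below_mac += 1
            continue
        stats.retained += 1
        sites.append(
            SnpSite(var.CHROM, var.POS, var.REF, var.ALT[0], var.ID or None)
        )
        columns.append(hap.astype(np.uint8))

    if stats.unphased:
        logger.warning("rejected %d records with unphased genotypes", stats.unphased)
    logger.info(
        "panel build: %d records, %d retained (%d non-SNP, %d unphased, "
        "%d missing, %d monomorphic, %d below MAC, %d outside mask)",
        stats.records, stats.retained, stats.non_snp, stats.unphased,
        stats.missing_genotype, stats.monomorphic, stats.below_mac,
        stats.outside_mask,
    )
    haplotypes = (
        np.stack(columns, axis=1) if columns else np.zeros((n_hap, 0), np.uint8)
    )
    if not sites:
        raise PanelError("no sites passed the panel filters")
    panel = ReferencePanel(
        sites,
        haplotypes,
        population_label=population_label,
        metadata={
            "source": str(vcf_source),
            "samples": list(sample_subset),
            "min_minor_count": int(min_minor_count),
            "masked": mask is not None,
        },
    )
    return (panel, stats) if return_stats else panel


# -- archive format --------------------------------------------------------
#
# A panel archive is a zip file containing:
#   meta.json   — format version, population label, shapes, metadata
#   sites.tsv   — chrom, pos (1-based), ref, alt, id
#   haps.bin    — np.packbits of the uint8 matrix, row-major


def save_panel(panel: ReferencePanel, path) -> None:
    """Write a panel archive (single zip file; see module source for layout)."""
    meta = {
        "format": "ldid-panel",
        "version": PANEL_FORMAT_VERSION,
        "population_label": panel.population_label,
        "n_haplotypes": panel.n_haplotypes,
        "n_sites": panel.n_sites,
        "metadata": panel.metadata,
    }
    lines = [
        f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t{s.site_id or '.'}"
        for s in panel.sites
    ]
    packed = np.packbits(panel.haplotypes, axis=None)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("sites.tsv", "\n".join(lines) + "\n")
        zf.writestr("haps.bin", packed.tobytes())


def load_panel(path) -> ReferencePanel:
    """Load a panel archive written by :func:`save_panel`."""
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format") != "ldid-panel":
                raise PanelError(f"{path}: not a panel archive")
            if meta.get("version") != PANEL_FORMAT_VERSION:
                raise PanelError(
                    f"{path}: unsupported panel format version {meta.get('version')}"
                )
            sites = []
            for line in zf.read("sites.tsv").decode().splitlines():
                chrom, pos, ref, alt, sid = line.split("\t")
                sites.append(
                    SnpSite(chrom, int(pos), ref, alt, None if sid == "." else sid)
                )
            n_hap, n_sites = meta["n_haplotypes"], meta["n_sites"]
            packed = np.frombuffer(zf.read("haps.bin"), dtype=np.uint8)
            haps = np.unpackbits(packed, count=n_hap * n_sites)
            haps = haps.reshape(n_hap, n_sites)
    except (zipfile.BadZipFile, KeyError, ValueError, EOFError) as exc:
        raise PanelError(f"{path}: corrupt or truncated panel archive: {exc}")
    if len(sites) != n_sites:
        raise PanelError(f"{path}: site table length mismatch")
    return ReferencePanel(
        sites,
        haps,
        population_label=meta["population_label"],
        metadata=meta.get("metadata", {}),
    )
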