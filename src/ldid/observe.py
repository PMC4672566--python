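"""Sparse single-base observations at panel SNP positions.

An observation is one base call at a known SNP position taken from exactly
one passing read — the method's atomic datum. Observations are extracted
from coordinate-sorted, indexed alignments (BAM/CRAM) or read from a plain
TSV, applying the same discard rules either way:

* sites covered by more than ``max_depth`` passing reads are omitted
  (multiple reads at a sparse-coverage site suggest mismapping);
* bases that match neither panel allele are discarded;
* in transversion-only mode, transition SNPs are skipped entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import ReferencePanel, is_transversion_site

logger = logging.getLogger(__name__)


class ObservationError(Exception):
    pass


@dataclass(frozen=True)
class Observation:
    """A single allele call: panel site index plus allele code (0=ref, 1=alt)."""

    site_index: int
    allele_code: int


@dataclass
class ObserveStats:
    """Counters for each filter rule applied during observation extraction."""

    sites_examined: int = 0
    skipped_transition: int = 0
    no_coverage: int = 0
    omitted_multiread: int = 0
    discarded_mismatch: int = 0
    emitted: int = 0


@dataclass
class ObservationSet:
    """Sparse per-sample observations tied to one specific panel.

    ``panel_fingerprint`` must match the panel used downstream; comparisons
    between observation sets made against different panels are refused.
    Site indices are strictly increasing (at most one observation per site).
    """

    sample_id: str
    panel_fingerprint: str
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [o.site_index for o in self.observations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ObservationError("site indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.observations)

    def site_indices(self) -> np.ndarray:
        return np.array([o.site_index for o in self.observations], dtype=np.int64)

    def allele_codes(self) -> np.ndarray:
        return np.array([o.allele_code for o in self.observations], dtype=np.uint8)


def observe_from_alignments(
    bam_source,
    panel: ReferencePanel,
    sample_id: str | None = None,
    min_base_q: int = 20,
    min_map_q: int = 30,
    max_depth: int = 1,
    transversions_only: bool = False,
    return_stats: bool = False,
):
    """Extract single-base observations at panel sites from mapped reads.

    For each panel site, reads with mapping quality >= ``min_map_q`` whose
    base at the site has quality >= ``min_base_q`` (and is not a deletion or
    reference skip) are counted. More than ``max_depth`` such reads omits
    the site; a single read whose base equals the panel ref or alt emits the
    corresponding allele code; other bases are discarded. Secondary,
    supplementary, QC-fail and duplicate-flagged reads are ignored.
    """
    import pysam

    bam = pysam.AlignmentFile(str(bam_source))
    if not bam.has_index():
        raise ObservationError(f"{bam_source}: missing index (.bai/.crai)")
    refs = set(bam.references)
    chrom_ranges = panel.chrom_ranges()
    for chrom in chrom_ranges:
        if chrom not in refs:
            hint = ""
            alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
            if alt in refs:
                hint = f" (alignments use {alt!r}; rename panel or BAM contigs)"
            raise ObservationError(
                f"panel chromosome {chrom!r} not in alignment header{hint}"
            )

    stats = ObserveStats()
    if sample_id is None:
        sample_id = str(bam_source)
    obs: list[Observation] = []
    for chrom, (start, stop) in chrom_ranges.items():
        for i in range(start, stop):
            site = panel.sites[i]
            if transversions_only and not is_transversion_site(site):
                stats.skipped_transition += 1
                continue
            stats.sites_examined += 1
            pos0 = site.pos - 1
            bases: list[str] = []
            for col in bam.pileup(
                chrom,
                pos0,
                pos0 + 1,
                truncate=True,
                min_base_quality=min_base_q,
                min_mapping_quality=min_map_q,
                ignore_overlaps=False,
                max_depth=10000,
            ):
                for pr in col.pileups:
                    if pr.is_del or pr.is_refskip:
                        continue
                    aln = pr.alignment
                    if aln.is_secondary or aln.is_supplementary:
                        continue
                    if aln.is_duplicate or aln.is_qcfail:
                        continue
                    bases.append(aln.query_sequence[pr.query_position])
            if not bases:
                stats.no_coverage += 1
                continue
            if len(bases) > max_depth:
                stats.omitted_multiread += 1
                continue
            if len(set(bases)) != 1:
                stats.discarded_mismatch += 1
                continue
            base = bases[0]
            if base == site.ref_allele:
                obs.append(Observation(i, 0))
            elif base == site.alt_allele:
                obs.append(Observation(i, 1))
            else:
                stats.discarded_mismatch += 1
                continue
            stats.emitted += 1
    bam.close()
    logger.info(
        "%s: %d sites examined, %d emitted, %d multi-read omitted, "
        "%d mismatch discarded, %d transition skipped",
        sample_id, stats.sites_examined, stats.emitted,
        stats.omitted_multiread, stats.discarded_mismatch,
        stats.skipped_transition,
    )
    obs_set = ObservationSet(sample_id, panel.fingerprint(), obs)
    return (obs_set, stats) if return_stats else obs_set


# -- TSV round-trip --------------------------------------------------------
#
# Dialect: tab-separated, '#'-prefixed header lines, no quoting. Columns:
# chrom, pos (1-based), base.


def write_observations_tsv(obs_set: ObservationSet, panel: ReferencePanel, path):
    """Write observations as chrom/pos/base rows with a commented header."""
    if obs_set.panel_fingerprint != panel.fingerprint():
        raise ObservationError("panel mismatch: fingerprint differs")
    with open(path, "w") as fh:
        fh.write(f"#sample_id={obs_set.sample_id}\n")
        fh.write(f"#panel_fingerprint={obs_set.panel_fingerprint}\n")
        fh.write("#chrom\tpos\tbase\n")
        for o in obs_set.observations:
            s = panel.sites[o.site_index]
            base = s.alt_allele if o.allele_code == 1 else s.ref_allele
            fh.write(f"{s.chrom}\t{s.pos}\t{base}\n")


def read_observations_tsv(
    path, panel: ReferencePanel, sample_id: str | None = None,
    return_stats: bool = False,
):
    """Read a chrom/pos/base TSV into an :class:`ObservationSet`.

    Rows at non-panel positions or with a base matching neither allele are
    rejected (counted); if a (chrom, pos) appears more than once, every copy
    of that site is dropped, mirroring the multi-read omission rule.
    """
    site_of = {
        (s.chrom, s.pos): i for i, s in enumerate(panel.sites)
    }
    header_sample = None
    rows: list[tuple[str, int, str, int]] = []  # chrom, pos, base, lineno
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#sample_id="):
                    header_sample = line.split("=", 1)[1]
                continue
            fields = line.split("\t")
            if len(fields) < 3 or fields[2] not in "ACGT" or len(fields[2]) != 1:
                raise ObservationError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                pos = int(fields[1])
            except ValueError:
                raise ObservationError(f"{path}:{lineno}: bad position {fields[1]!r}")
            rows.append((fields[0], pos, fields[2], lineno))

    seen: dict[tuple[str, int], int] = {}
    for chrom, pos, _, _ in rows:
        seen[(chrom, pos)] = seen.get((chrom, pos), 0) + 1

    rejected_offpanel = rejected_mismatch = dropped_duplicate = 0
    by_index: dict[int, int] = {}
    for chrom, pos, base, lineno in rows:
        if seen[(chrom, pos)] > 1:
            dropped_duplicate += 1
            continue
        idx = site_of.get((chrom, pos))
        if idx is None:
            rejected_offpanel += 1
            continue
        s = panel.sites[idx]
        if base == s.ref_allele:
            by_index[idx] = 0
        elif base == s.alt_allele:
            by_index[idx] = 1
        else:
            rejected_mismatch += 1
    if rejected_offpanel or rejected_mismatch or dropped_duplicate:
        logger.info(
            "%s: rejected %d off-panel, %d allele-mismatch rows; "
            "dropped %d duplicated-site rows",
            path, rejected_offpanel, rejected_mismatch, dropped_duplicate,
        )
    obs = [Observation(i, by_index[i]) for i in sorted(by_index)]
    obs_set = ObservationSet(
        sample_id or header_sample or str(path), panel.fingerprint(), obs
    )
    if return_stats:
        return obs_set, {
            "rejected_offpanel": rejected_offpanel,
            "rejected_mismatch": rejected_mismatch,
            "dropped_duplicate": dropped_duplicate,
        }
    return obs_set


def subsample_observations(
    obs_set: ObservationSet, rate: float, seed: int
) -> ObservationSet:
    """Keep each observation independently with probability ``rate`` (seeded)."""
    if not 0.0 < rate <= 1.0:
        raise ValueError(f"rate must be in (0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(obs_set.observations)) < rate
    kept = [o for o, k in zip(obs_set.observations, keep) if k]
    return ObservationSet(obs_set.sample_id, obs_set.panel_fingerprint, kept)
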