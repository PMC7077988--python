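"""Selection and mutation of genomic candidate regulatory elements.

Mirrors the genomic wild-type (gWT) pipeline: scan sequences with the four
pluripotency PWMs at p <= 1e-3, keep hits near anchor peaks (e.g. ChIP-seq
binding regions), drop regions with overlapping hits, single-linkage merge
hits closer than 20 bp into clusters, keep clusters of exactly three sites
for three distinct TFs, expand symmetrically to 81-82 bp centered on the
motif span, rescan to confirm the selection is self-consistent, and design
the matched mutant (gMUT) sequence by the two-position site-killing rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .library_design import DEFAULT_RESTRICTION_SITES, design_mutant_site, FORWARD, REVERSE
from .motifs import MotifModel, SiteHit
from ._seq import revcomp

logger = logging.getLogger(__name__)


@dataclass
class SiteCluster:
    """A merged group of motif hits on one source sequence."""

    sequence_id: str
    hits: list[SiteHit]

    @property
    def start(self) -> int:
        return min(h.start for h in self.hits)

    @property
    def end(self) -> int:
        return max(h.end for h in self.hits)

    @property
    def tfs(self) -> tuple[str, ...]:
        return tuple(h.tf for h in sorted(self.hits, key=lambda h: h.start))


@dataclass
class GenomicElement:
    """An 81-82 bp genomic interval with exactly one site per present TF."""

    element_id: str
    sequence_id: str
    start: int
    end: int
    sites: list[SiteHit]  # element-local coordinates
    wt_sequence: str
    mut_sequence: str | None = None
    status: str = "ok"

    @property
    def composition(self) -> frozenset[str]:
        return frozenset(h.tf for h in self.sites)

    @property
    def configuration(self) -> str:
        """Orientation-aware 5'→3' site string, e.g. ``"O-k-E"``."""
        ordered = sorted(self.sites, key=lambda h: h.start)
        return "-".join(h.tf if h.strand == "+" else h.tf.lower() for h in ordered)

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_and_cluster(
    sequences: Mapping[str, str],
    motifs: Sequence[MotifModel] | Mapping[str, MotifModel],
    p_threshold: float = 1e-3,
    merge_gap: int = 20,
    anchor_peaks: pd.DataFrame | None = None,
    anchor_window: int = 100,
) -> list[SiteCluster]:
    """Scan, anchor-filter, and merge motif hits into site clusters.

    Hits whose interval lies within ``anchor_window`` bp of any anchor peak
    (same sequence) are kept; with ``anchor_peaks=None`` everything is
    scanned.  Hits with edge-to-edge gap < ``merge_gap`` are single-linkage
    merged.  A cluster containing any two overlapping hits is excluded
    outright (the whole region is dropped).
    """
    motif_list = list(motifs.values()) if isinstance(motifs, Mapping) else list(motifs)
    anchors_by_seq: dict[str, list[tuple[int, int]]] = {}
    if anchor_peaks is not None:
        required = {"chrom", "start", "end"}
        if not required.issubset(anchor_peaks.columns):
            raise ValueError(f"anchor_peaks must have columns {sorted(required)}")
        for row in anchor_peaks.itertuples():
            anchors_by_seq.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))

    clusters: list[SiteCluster] = []
    for sid in sorted(sequences):
        seq = sequences[sid]
        hits = [h for m in motif_list for h in m.scan(seq, p_threshold, sequence_id=sid)]
        if anchor_peaks is not None:
            peaks = anchors_by_seq.get(sid, [])
            hits = [
                h
                for h in hits
                if any(h.start < pe + anchor_window and h.end > ps - anchor_window for ps, pe in peaks)
            ]
        hits.sort(key=lambda h: (h.start, h.end, h.strand, h.tf))
        current: list[SiteHit] = []
        cur_end = None
        groups: list[list[SiteHit]] = []
        for h in hits:
            if cur_end is None or h.start - cur_end < merge_gap:
                current.append(h)
                cur_end = max(cur_end, h.end) if cur_end is not None else h.end
            else:
                groups.append(current)
                current, cur_end = [h], h.end
        if current:
            groups.append(current)
        for grp in groups:
            grp_sorted = sorted(grp, key=lambda h: h.start)
            overlapping = any(
                b.start < a.end for a, b in zip(grp_sorted, grp_sorted[1:])
            )
            if overlapping:
                logger.info("dropping cluster on %s at %d: overlapping sites", sid, grp_sorted[0].start)
                continue
            clusters.append(SiteCluster(sid, grp_sorted))
    return clusters


def _expand_span(start: int, end: int, seq_len: int, target: int = 81) -> tuple[int, int] | None:
    """Symmetric expansion of [start, end) to ``target`` (or target+1) bp.

    Pads equally on both sides of the motif span; when target − span is
    odd, both pads are rounded up, giving an 82 bp interval, so the span
    stays exactly centered.  Returns None if the expansion leaves the
    sequence bounds.
    """
    span = end - start
    if span > target + 1:
        return None
    pad = (target - span + 1) // 2
    lo, hi = start - pad, end + pad
    if lo < 0 or hi > seq_len:
        return None
    return lo, hi


def select_elements(
    clusters: Sequence[SiteCluster],
    sequences: Mapping[str, str],
    motifs: Sequence[MotifModel] | Mapping[str, MotifModel],
    p_threshold: float = 1e-3,
    n_sites: int = 3,
    target_length: int = 81,
    restriction_sites: Mapping[str, str] = DEFAULT_RESTRICTION_SITES,
) -> list[GenomicElement]:
    """Composition-filter, expand and rescan clusters into elements.

    A cluster survives if it has exactly ``n_sites`` sites for ``n_sites``
    distinct TFs; the expanded sequence must rescan to exactly the same
    number of hits with no duplicated TF, and must not contain a
    restriction site.  Output order is deterministic (sequence id, start).
    """
    motif_list = list(motifs.values()) if isinstance(motifs, Mapping) else list(motifs)
    elements: list[GenomicElement] = []
    for cl in sorted(clusters, key=lambda c: (c.sequence_id, c.start)):
        if len(cl.hits) != n_sites or len({h.tf for h in cl.hits}) != n_sites:
            continue
        seq = sequences[cl.sequence_id]
        span = _expand_span(cl.start, cl.end, len(seq), target=target_length)
        if span is None:
            logger.info("dropping cluster on %s at %d: expansion out of bounds", cl.sequence_id, cl.start)
            continue
        lo, hi = span
        wt = seq[lo:hi]
        if any(s in wt or revcomp(s) in wt for s in restriction_sites.values()):
            logger.info("dropping cluster on %s at %d: restriction site", cl.sequence_id, cl.start)
            continue
        rescan = [h for m in motif_list for h in m.scan(wt, p_threshold, sequence_id=cl.sequence_id)]
        rescan.sort(key=lambda h: h.start)
        if len(rescan) != n_sites or len({h.tf for h in rescan}) != n_sites:
            logger.info(
                "dropping cluster on %s at %d: rescan found %d hits", cl.sequence_id, cl.start, len(rescan)
            )
            continue
        eid = f"{cl.sequence_id}:{lo}-{hi}"
        local = [replace(h, sequence_id=eid, start=h.start, end=h.end) for h in rescan]
        elements.append(GenomicElement(eid, cl.sequence_id, lo, hi, local, wt))
    return elements


def mutate_genomic_element(
    element: GenomicElement,
    motifs: Mapping[str, MotifModel],
    p_threshold: float = 1e-3,
) -> GenomicElement:
    """Fill ``mut_sequence`` by killing every site with two substitutions.

    Each site is mutated strand-aware via the two-highest-information-
    position rule, so wt and mut differ at exactly 2 x n_sites positions.
    The mutant is rescanned with all motifs; any remaining hit marks the
    element ``failed_verification`` instead of silently passing.
    """
    if not element.sites:
        raise ValueError("element has no annotated sites")
    ordered = sorted(element.sites, key=lambda h: h.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise RuntimeError("overlapping site coordinates in accepted element")
    seq = list(element.wt_sequence)
    for h in ordered:
        site_seq = element.wt_sequence[h.start : h.end]
        mut = design_mutant_site(
            site_seq,
            motifs[h.tf],
            orientation=FORWARD if h.strand == "+" else REVERSE,
            p_threshold=p_threshold,
        )
        seq[h.start : h.end] = list(mut.sequence)
    mut_seq = "".join(seq)
    leftover = [
        h for m in motifs.values() for h in m.scan(mut_seq, p_threshold)
    ]
    status = "ok" if not leftover else "failed_verification"
    return replace(element, mut_sequence=mut_seq, status=status)


# ------------------------------------------------------------------ file IO


def elements_to_bed(elements: Sequence[GenomicElement]) -> pd.DataFrame:
    """Elements as a BED-style frame (chrom, start, end, name, score, strand)."""
    return pd.DataFrame(
        [
            (e.sequence_id, e.start, e.end, e.configuration, len(e.sites), "+")
            for e in elements
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )


def elements_manifest(elements: Sequence[GenomicElement]) -> pd.DataFrame:
    """Per-site annotation manifest for a selected element set."""
    rows = []
    for e in elements:
        for h in sorted(e.sites, key=lambda h: h.start):
            rows.append(
                (e.element_id, e.sequence_id, e.start, e.end, e.configuration,
                 h.tf, h.start, h.end, h.strand, h.score, h.pvalue, e.status)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "element_id", "chrom", "element_start", "element_end", "configuration",
            "tf", "site_start", "site_end", "site_strand", "site_score", "site_pvalue", "status",
        ],
    )


def write_element_fastas(elements: Sequence[GenomicElement], wt_path, mut_path=None) -> None:
    with open(wt_path, "w") as fh:
        for e in elements:
            fh.write(f">{e.element_id}\n{e.wt_sequence}\n")
    if mut_path is not None:
        with open(mut_path, "w") as fh:
            for e in elements:
                if e.mut_sequence is not None:
                    fh.write(f">{e.element_id}\n{e.mut_sequence}\n")
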