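"""Design of combinatorial synthetic reporter libraries.

The synthetic (SYN) library enumerates every ordered arrangement of 2, 3 or
4 distinct pluripotency binding sites (OCT4 = O, SOX2 = S, KLF4 = K,
ESRRB = E), each independently in forward or reverse orientation: 48
two-site + 192 three-site + 384 four-site = 624 elements.  Element ids use
capital letters for forward sites and lower-case for reverse (``"S-O-k-e"``).
Each element's sites are embedded in constant 20-bp building blocks with
fixed spacing, concatenated into the [SEQ] slot of a 150-bp oligo scaffold
with a random filler, a 9-bp barcode, and fixed cloning arms.  The module
also designs the site-killing double mutations used for genomic mutant
(gMUT) sequences and the mini library that swaps the spacer sequence
flanking the sites.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import BASES, hamming, revcomp
from .motifs import MotifModel

#: canonical TF order used for deterministic enumeration
TF_ORDER = ("O", "S", "K", "E")

FORWARD, REVERSE = "forward", "reverse"

#: restriction sites screened out of variable oligo segments: the cloning
#: enzymes ApaI, SacI, HindIII, EcoRI, XbaI plus SpeI
DEFAULT_RESTRICTION_SITES = {
    "ApaI": "GGGCCC",
    "SacI": "GAGCTC",
    "HindIII": "AAGCTT",
    "EcoRI": "GAATTC",
    "XbaI": "TCTAGA",
    "SpeI": "ACTAGT",
}

SYN_SCAFFOLD = "CTTCTACTACTAGGGCCCA[SEQ]AAGCTT[FILL]GAATTCTCTAGAC[BC]TGAGCTCTACATGCTAGTTCATG"
GENOMIC_SCAFFOLD = "GACTTACATTAGGGCCCGT[SEQ]AAGCTT[FILL]GAATTCTCTAGAC[BC]TGAGCTCGGACTACGATACTG"
MINI_SPACER_SCAFFOLD = (
    "GACATCAAGATCTGGCCTCGGGGCCC[SEQ]AAGCTTGAATTCTCTAGAC[BC]TGAGCTCTCGCTTCGAGCAGACATGAT"
)

SYN_OLIGO_LENGTH = 150
MINI_SPACER_OLIGO_LENGTH = 161
BARCODE_LENGTH = 9


# ----------------------------------------------------------------- elements


@dataclass(frozen=True)
class SynElement:
    """An ordered arrangement of distinct, oriented binding sites."""

    sites: tuple[tuple[str, str], ...]  # ((tf, orientation), ...)
    sequence: str | None = None

    def __post_init__(self):
        tfs = [tf for tf, _ in self.sites]
        if len(set(tfs)) != len(tfs):
            raise ValueError(f"duplicate TF in element: {tfs}")
        if not 2 <= len(tfs) <= 4:
            raise ValueError(f"element must have 2-4 sites, got {len(tfs)}")
        for tf, orient in self.sites:
            if orient not in (FORWARD, REVERSE):
                raise ValueError(f"bad orientation {orient!r}")

    @property
    def k(self) -> int:
        return len(self.sites)

    @property
    def element_id(self) -> str:
        return "-".join(tf if o == FORWARD else tf.lower() for tf, o in self.sites)

    @classmethod
    def from_id(cls, element_id: str, sequence: str | None = None) -> "SynElement":
        sites = tuple(
            (tok.upper(), FORWARD if tok.isupper() else REVERSE)
            for tok in element_id.split("-")
        )
        return cls(sites, sequence)


def enumerate_syn_elements(
    tf_set: Sequence[str] = TF_ORDER, k_values: Iterable[int] = (2, 3, 4)
) -> list[SynElement]:
    """Every ordered selection of k distinct TFs, each independently oriented.

    Output is deterministic: k ascending, then permutations in canonical TF
    order, then orientations with forward before reverse.  Counts are
    Σ_k P(4,k)·2^k = 48 + 192 + 384 = 624 for the default inputs.
    """
    tfs = tuple(tf_set)
    if len(set(tfs)) != len(tfs):
        raise ValueError(f"duplicate TFs in tf_set: {tfs}")
    if len(tfs) != 4:
        raise ValueError("tf_set must contain exactly 4 TFs")
    canonical = tuple(sorted(tfs, key=lambda t: (TF_ORDER.index(t) if t in TF_ORDER else 99, t)))
    out = []
    for k in sorted(set(k_values)):
        for perm in itertools.permutations(canonical, k):
            for orients in itertools.product((FORWARD, REVERSE), repeat=k):
                out.append(SynElement(tuple(zip(perm, orients))))
    return out


# ------------------------------------------------------------------- blocks


@dataclass(frozen=True)
class BuildingBlock:
    """A 20-bp constant block containing one binding site.

    ``site_start``/``site_length`` locate the TFBS within the forward-
    orientation block; a reverse-orientation site uses the reverse
    complement of the whole block, so the flanking spacer travels with the
    site.
    """

    tf: str
    sequence: str
    site_start: int
    site_length: int

    def __post_init__(self):
        if len(self.sequence) != 20:
            raise ValueError(f"building block must be 20 bp, got {len(self.sequence)}")
        if not 0 <= self.site_start <= 20 - self.site_length:
            raise ValueError("site does not fit in block")

    @property
    def site(self) -> str:
        return self.sequence[self.site_start : self.site_start + self.site_length]

    def oriented(self, orientation: str) -> str:
        return self.sequence if orientation == FORWARD else revcomp(self.sequence)


def element_insert(element: SynElement, blocks: Mapping[str, BuildingBlock]) -> str:
    """The [SEQ] insert: the element's oriented blocks concatenated 5'→3'."""
    return "".join(blocks[tf].oriented(orient) for tf, orient in element.sites)


# ----------------------------------------------------------------- scaffold


_SLOT_RE = re.compile(r"\[(SEQ|FILL|BC)\]")


class OligoDesignError(ValueError):
    pass


class BarcodeError(OligoDesignError):
    """A barcode that cannot be used in this scaffold context."""


@dataclass(frozen=True)
class Scaffold:
    """An oligo template with [SEQ], [FILL] and [BC] slots."""

    template: str
    total_length: int

    @property
    def fixed_length(self) -> int:
        return len(_SLOT_RE.sub("", self.template))

    @property
    def slots(self) -> list[str]:
        return _SLOT_RE.findall(self.template)

    def fill_length(self, seq_len: int, barcode_len: int = BARCODE_LENGTH) -> int:
        n = self.total_length - self.fixed_length - seq_len - barcode_len
        if "[FILL]" not in self.template:
            if n != 0:
                raise OligoDesignError(
                    f"insert of {seq_len} bp does not fit a fill-less {self.total_length} bp scaffold"
                )
            return 0
        if n < 0:
            raise OligoDesignError(
                f"insert of {seq_len} bp too long for {self.total_length} bp scaffold"
            )
        return n

    def assemble(self, seq: str, fill: str, barcode: str) -> tuple[str, dict[str, tuple[int, int]]]:
        """Substitute the slots; returns (oligo, slot spans in oligo coords)."""
        parts = _SLOT_RE.split(self.template)
        # parts alternates fixed text and slot names
        values = {"SEQ": seq, "FILL": fill, "BC": barcode}
        out, spans, pos = [], {}, 0
        for i, part in enumerate(parts):
            if i % 2 == 1:
                spans[part] = (pos, pos + len(values[part]))
                out.append(values[part])
                pos += len(values[part])
            else:
                out.append(part)
                pos += len(part)
        return "".join(out), spans


SYN = Scaffold(SYN_SCAFFOLD, SYN_OLIGO_LENGTH)
GENOMIC = Scaffold(GENOMIC_SCAFFOLD, SYN_OLIGO_LENGTH)
MINI_SPACER = Scaffold(MINI_SPACER_SCAFFOLD, MINI_SPACER_OLIGO_LENGTH)


@dataclass(frozen=True)
class OligoRecord:
    """One synthesized oligo: element, barcode, and the final sequence."""

    element_id: str
    barcode: str
    scaffold: Scaffold
    oligo: str
    role: str  # syn | gwt | gmut | basal | spacer_variant

    def __post_init__(self):
        if len(self.oligo) != self.scaffold.total_length:
            raise ValueError(
                f"oligo length {len(self.oligo)} != scaffold length {self.scaffold.total_length}"
            )


def find_restriction_violations(
    oligo: str,
    variable_spans: Mapping[str, tuple[int, int]],
    restriction_sites: Mapping[str, str] = DEFAULT_RESTRICTION_SITES,
) -> list[tuple[str, int]]:
    """Occurrences of restriction sites that touch a variable segment.

    Sites wholly inside the fixed scaffold are the intended cloning sites
    and are allowed; any occurrence overlapping [SEQ], [FILL] or [BC] (on
    either strand) is a violation.
    """
    spans = list(variable_spans.values())
    bad = []
    for enzyme, site in restriction_sites.items():
        for probe in {site, revcomp(site)}:
            start = oligo.find(probe)
            while start != -1:
                end = start + len(probe)
                if any(start < s_end and end > s_start for s_start, s_end in spans):
                    bad.append((enzyme, start, end))
                start = oligo.find(probe, start + 1)
    return sorted(set(bad))


def _random_clean_fill(
    length: int,
    rng: np.random.Generator,
    context: tuple[str, str],
    restriction_sites: Mapping[str, str],
    max_tries: int = 200,
) -> str:
    """Random filler that creates no restriction site, given fixed context."""
    if length == 0:
        return ""
    left, right = context
    pad = max((len(s) for s in restriction_sites.values()), default=6) - 1
    for _ in range(max_tries):
        fill = "".join(BASES[c] for c in rng.integers(0, 4, size=length))
        window = left[-pad:] + fill + right[:pad]
        if not any(
            s in window or revcomp(s) in window for s in restriction_sites.values()
        ):
            return fill
    raise OligoDesignError(f"could not generate a clean {length} bp filler")


def assemble_oligo(
    element_id: str,
    seq_insert: str,
    barcode: str,
    scaffold: Scaffold = SYN,
    role: str = "syn",
    rng: np.random.Generator | None = None,
    fill: str | None = None,
    restriction_sites: Mapping[str, str] = DEFAULT_RESTRICTION_SITES,
) -> OligoRecord:
    """Assemble one oligo from a [SEQ] insert and a barcode.

    The [FILL] slot is sized to pad the oligo to the scaffold's total
    length; if ``fill`` is not supplied a random, restriction-clean filler
    is drawn from ``rng``.  A barcode that creates a restriction site is
    rejected (the caller must resupply one).
    """
    if len(barcode) != BARCODE_LENGTH:
        raise OligoDesignError(f"barcode must be {BARCODE_LENGTH} bp, got {len(barcode)}")
    n_fill = scaffold.fill_length(len(seq_insert))
    if fill is None:
        if rng is None:
            rng = np.random.default_rng(0)
        # fixed/variable context on either side of the [FILL] slot
        parts = _SLOT_RE.split(scaffold.template)
        left, right, seen_fill = [], [], False
        for i, part in enumerate(parts):
            if i % 2 == 1 and part == "FILL":
                seen_fill = True
                continue
            text = part if i % 2 == 0 else (seq_insert if part == "SEQ" else barcode)
            (right if seen_fill else left).append(text)
        fill = _random_clean_fill(
            n_fill, rng, ("".join(left), "".join(right)), restriction_sites
        )
    elif len(fill) != n_fill:
        raise OligoDesignError(f"fill must be {n_fill} bp, got {len(fill)}")
    oligo, spans = scaffold.assemble(seq_insert, fill, barcode)
    violations = find_restriction_violations(oligo, spans, restriction_sites)
    bc_span = spans["BC"]
    bc_violations = [
        v for v in violations if v[1] < bc_span[1] and v[2] > bc_span[0]
    ]
    if bc_violations:
        raise BarcodeError(f"barcode {barcode} creates restriction site(s): {bc_violations}")
    if violations:
        raise OligoDesignError(f"oligo for {element_id} has restriction site(s): {violations}")
    return OligoRecord(element_id, barcode, scaffold, oligo, role)


# ----------------------------------------------------------------- barcodes


def barcode_stream(
    seed: int | np.random.Generator = 0,
    length: int = BARCODE_LENGTH,
    restriction_sites: Mapping[str, str] = DEFAULT_RESTRICTION_SITES,
    max_homopolymer: int = 4,
    min_hamming: int = 2,
    existing: Iterable[str] = (),
):
    """Endless stream of screened random barcodes.

    Candidates are uniform random ``length``-mers; a candidate is rejected
    if it contains a homopolymer run longer than ``max_homopolymer``, any
    restriction site (either strand), or lies within Hamming distance
    ``min_hamming`` − 1 of an already yielded (or ``existing``) barcode.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    homopoly = re.compile("|".join(b * (max_homopolymer + 1) for b in BASES))
    probes = set()
    for s in restriction_sites.values():
        probes.add(s)
        probes.add(revcomp(s))

    used: set[str] = set(existing)

    def neighbors(bc: str):
        for i, base in enumerate(bc):
            for b in BASES:
                if b != base:
                    yield bc[:i] + b + bc[i + 1 :]

    stall = 0
    while True:
        stall += 1
        if stall > 100000:
            raise OligoDesignError("barcode generation stalled; relax the screens")
        bc = "".join(BASES[c] for c in rng.integers(0, 4, size=length))
        if homopoly.search(bc):
            continue
        if any(p in bc for p in probes):
            continue
        if bc in used:
            continue
        if min_hamming >= 2 and any(nb in used for nb in neighbors(bc)):
            continue
        used.add(bc)
        stall = 0
        yield bc


def generate_barcodes(
    n: int,
    seed: int | np.random.Generator = 0,
    length: int = BARCODE_LENGTH,
    restriction_sites: Mapping[str, str] = DEFAULT_RESTRICTION_SITES,
    max_homopolymer: int = 4,
    min_hamming: int = 2,
    existing: Iterable[str] = (),
) -> list[str]:
    """``n`` screened random barcodes (see :func:`barcode_stream`)."""
    stream = barcode_stream(
        seed, length, restriction_sites, max_homopolymer, min_hamming, existing
    )
    return [next(stream) for _ in range(n)]


# ------------------------------------------------------------------- pools


def build_syn_pool(
    elements: Sequence[SynElement],
    blocks: Mapping[str, BuildingBlock],
    barcodes_per_element: int = 8,
    n_basal: int = 112,
    seed: int = 0,
    scaffold: Scaffold = SYN,
    restriction_sites: Mapping[str, str] = DEFAULT_RESTRICTION_SITES,
) -> list[OligoRecord]:
    """The full SYN pool: every element × 8 barcodes plus 112 basal oligos.

    Basal records carry an empty [SEQ] (minimal promoter only); all padding
    goes to [FILL].  Barcodes are unique across the whole pool; a barcode
    that creates a restriction site against its scaffold context is
    discarded and replaced from the stream.
    """
    rng = np.random.default_rng(seed)
    barcodes = barcode_stream(rng, restriction_sites=restriction_sites)
    records = []
    for el in elements:
        insert = element_insert(el, blocks)
        for _ in range(barcodes_per_element):
            records.append(
                _assemble_with_fresh_barcode(
                    el.element_id, insert, barcodes, scaffold, "syn", rng, restriction_sites
                )
            )
    for _ in range(n_basal):
        records.append(
            _assemble_with_fresh_barcode(
                "basal", "", barcodes, scaffold, "basal", rng, restriction_sites
            )
        )
    return records


def _assemble_with_fresh_barcode(
    element_id, insert, barcodes, scaffold, role, rng, restriction_sites, max_tries=50
):
    for _ in range(max_tries):
        try:
            return assemble_oligo(
                element_id, insert, next(barcodes), scaffold=scaffold, role=role,
                rng=rng, restriction_sites=restriction_sites,
            )
        except BarcodeError:
            continue
    raise OligoDesignError(f"no usable barcode found for {element_id}")


# ----------------------------------------------------------------- mutation


@dataclass(frozen=True)
class MutantSite:
    """Result of the two-position site-killing mutation."""

    sequence: str
    positions: tuple[int, int]  # 0-based, in the supplied site's frame
    status: str  # "ok" or "needs_review"


def design_mutant_site(
    site_sequence: str,
    motif: MotifModel,
    orientation: str = FORWARD,
    p_threshold: float = 1e-3,
) -> MutantSite:
    """Mutate the two highest-information positions to the rarest base.

    The two positions with the highest information content (ties broken
    5'-most in the motif frame) are changed to the lowest-frequency base of
    that PFM column (ties broken alphabetically; if the site already
    carries that base the next-rarest is used, so exactly two positions
    always change).  A reverse-orientation site is mutated through the
    reverse-complement mapping.  The mutant is rescanned; if any window
    still hits at ``p_threshold`` the result is flagged ``needs_review``
    rather than silently accepted.
    """
    if motif.length < 2:
        raise ValueError("motif must have at least 2 positions")
    if len(site_sequence) != motif.length:
        raise ValueError(
            f"site length {len(site_sequence)} != motif length {motif.length}"
        )
    work = site_sequence if orientation == FORWARD else revcomp(site_sequence)
    order = np.lexsort((np.arange(motif.length), -motif.ic))
    targets = sorted(int(i) for i in order[:2])
    bases = list(work)
    for pos in targets:
        col = motif.pfm[:, pos]
        for b in sorted(range(4), key=lambda i: (col[i], BASES[i])):
            if BASES[b] != bases[pos]:
                bases[pos] = BASES[b]
                break
    mutated = "".join(bases)
    if orientation == REVERSE:
        mutated = revcomp(mutated)
        targets = sorted(motif.length - 1 - t for t in targets)
    status = "ok" if not motif.scan(mutated, p_threshold=p_threshold) else "needs_review"
    return MutantSite(mutated, (targets[0], targets[1]), status)


# ------------------------------------------------------------- mini spacer


class SpacerDesignError(ValueError):
    pass


def generate_spacer_alternatives(
    blocks: Mapping[str, BuildingBlock],
    motifs: Mapping[str, MotifModel],
    n_alternatives: int = 4,
    seed: int = 0,
    p_threshold: float = 1e-3,
    restriction_sites: Mapping[str, str] = DEFAULT_RESTRICTION_SITES,
    max_tries: int = 500,
) -> dict[str, dict[str, BuildingBlock]]:
    """Alternative block tables with shuffled flanking (spacer) sequence.

    Each alternative keeps every binding site untouched and permutes the
    flanking bases of each block (preserving nucleotide composition, per
    the design intent of matching the original spacers' content), then is
    screened so the new flanks create no pluripotency site at the scanning
    threshold and no restriction site.
    """
    rng = np.random.default_rng(seed)

    def clean_block(tf: str, block: BuildingBlock) -> BuildingBlock:
        for _ in range(max_tries):
            flank = list(
                block.sequence[: block.site_start]
                + block.sequence[block.site_start + block.site_length :]
            )
            rng.shuffle(flank)
            left = "".join(flank[: block.site_start])
            right = "".join(flank[block.site_start :])
            seq = left + block.site + right
            if seq == block.sequence:
                continue
            if any(s in seq or revcomp(s) in seq for s in restriction_sites.values()):
                continue
            hits = [h for m in motifs.values() for h in m.scan(seq, p_threshold)]
            extra = [h for h in hits if (h.start, h.tf) != (block.site_start, tf)]
            if extra or not any(h.tf == tf for h in hits):
                continue
            return BuildingBlock(tf, seq, block.site_start, block.site_length)
        raise SpacerDesignError(f"could not shuffle a clean spacer for {tf}")

    def junctions_clean(table: Mapping[str, BuildingBlock]) -> bool:
        # every ordered pair of oriented blocks must stay clean when
        # concatenated (no junction-created motif or restriction site)
        oriented = {}
        for tf, b in table.items():
            oriented[(tf, FORWARD)] = (b.oriented(FORWARD), {(b.site_start, tf)})
            oriented[(tf, REVERSE)] = (
                b.oriented(REVERSE),
                {(20 - b.site_start - b.site_length, tf)},
            )
        for (tfa, _), (sa, expa) in oriented.items():
            for (tfb, _), (sb, expb) in oriented.items():
                if tfa == tfb:
                    continue
                cat = sa + sb
                if any(
                    s in cat or revcomp(s) in cat for s in restriction_sites.values()
                ):
                    return False
                exp = set(expa) | {(s + 20, tf) for s, tf in expb}
                for m in motifs.values():
                    if any((h.start, h.tf) not in exp for h in m.scan(cat, p_threshold)):
                        return False
        return True

    out: dict[str, dict[str, BuildingBlock]] = {}
    for a in range(n_alternatives):
        name = f"alt{a + 1}"
        for _ in range(max_tries):
            table = {tf: clean_block(tf, block) for tf, block in blocks.items()}
            if junctions_clean(table):
                out[name] = table
                break
        else:
            raise SpacerDesignError(f"could not build a junction-clean spacer set {name}")
    return out


@dataclass
class MiniSpacerLibrary:
    records: list[OligoRecord]
    rejected: list[tuple[str, str, str]]  # (element_id, spacer, reason)

    @property
    def n_constructs(self) -> int:
        return len({r.element_id for r in self.records})


def build_mini_spacer_library(
    elements: Sequence[SynElement],
    blocks: Mapping[str, BuildingBlock],
    spacer_alternatives: Mapping[str, Mapping[str, BuildingBlock]],
    motifs: Mapping[str, MotifModel] | None = None,
    barcodes_per_construct: int = 5,
    seed: int = 0,
    p_threshold: float = 1e-3,
    restriction_sites: Mapping[str, str] = DEFAULT_RESTRICTION_SITES,
) -> MiniSpacerLibrary:
    """One construct per (element, spacer) pair, 5 barcodes each.

    The spacer set is the original block table plus the supplied
    alternatives, so 6 elements × (4 + 1) spacers = 30 constructs = 150
    oligos under the default design.  If ``motifs`` is given, a spacer whose
    insert gains an unintended pluripotency site is rejected and reported.
    """
    spacer_sets: dict[str, Mapping[str, BuildingBlock]] = {"original": blocks}
    spacer_sets.update(spacer_alternatives)
    rng = np.random.default_rng(seed)
    records: list[OligoRecord] = []
    rejected: list[tuple[str, str, str]] = []
    barcodes = barcode_stream(rng, restriction_sites=restriction_sites)
    for el in elements:
        for spacer_name, table in spacer_sets.items():
            insert = element_insert(el, table)
            if motifs is not None:
                hits = [h for m in motifs.values() for h in m.scan(insert, p_threshold)]
                if len(hits) != el.k or {h.tf for h in hits} != {tf for tf, _ in el.sites}:
                    rejected.append(
                        (el.element_id, spacer_name, f"unexpected hit set: {len(hits)} hits")
                    )
                    continue
            cid = f"{el.element_id}|{spacer_name}"
            for _ in range(barcodes_per_construct):
                records.append(
                    _assemble_with_fresh_barcode(
                        cid, insert, barcodes, MINI_SPACER, "spacer_variant",
                        rng, restriction_sites,
                    )
                )
    return MiniSpacerLibrary(records, rejected)


# --------------------------------------------------------------- manifests


def pool_manifest(records: Sequence[OligoRecord]):
    """TSV-ready manifest (element_id, role, barcode, oligo) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [(r.element_id, r.role, r.barcode, r.oligo) for r in records],
        columns=["element_id", "role", "barcode", "oligo"],
    )


def write_pool(records: Sequence[OligoRecord], fasta_path, manifest_path) -> None:
    """Write a pool as FASTA (oligo per barcode) plus a TSV manifest."""
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.element_id}|{r.barcode}\n{r.oligo}\n")
    pool_manifest(records).to_csv(manifest_path, sep="\t", index=False)
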