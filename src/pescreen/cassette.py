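"""Deconvolution of pegRNA-ST cassette reads.

Read 1 covers the pegRNA (protospacer, scaffold, 3' extension); read 2 covers
the 55-nt surrogate target (ST), the 16-nt pegRNA barcode and the 10-nt
library barcode. Each element is sliced at fixed offsets, matched against the
library with up to 10% substitutions per element, and a read is assigned to a
pegRNA only when every element agrees on a single identity. Reads whose
elements confidently match *different* pegRNAs are recombinants (lentiviral
template switching / synthesis chimeras) and are discarded. The ST is matched
only by its invariant 3' end so that edited STs are not thrown away; correct
editing is then scored by exact containment of the intended edit plus 5-nt
flanks.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import PegRNADesign, SchemaError, ScreenConfig

logger = logging.getLogger(__name__)

ELEMENT_NAMES = ("spacer", "scaffold", "extension", "st_read",
                 "pegrna_bc", "library_bc")

#: length of the invariant ST 3' suffix used for identity cross-checking
DEFAULT_ST_CHECK_LEN = 15


@dataclass(frozen=True)
class Reject:
    reason: str  # too_short | anchor_not_found


@dataclass(frozen=True)
class ElementSet:
    spacer: str
    scaffold: str
    extension: str
    st_read: str
    pegrna_bc: str
    library_bc: str

    def as_dict(self) -> Dict[str, str]:
        return {name: getattr(self, name) for name in ELEMENT_NAMES}


@dataclass
class CassetteLayout:
    """Per-element (offset, length) slices within each read of the pair.

    ``anchor1``/``anchor2`` are optional fixed sequences expected at
    ``anchor*_offset`` in the respective read; if given, each read is scanned
    for an exact anchor occurrence within ``+/- anchor_window`` nt and all
    slices in that read are shifted accordingly.
    """

    read1_elements: Sequence[Tuple[str, int, int]]
    read2_elements: Sequence[Tuple[str, int, int]]
    st_check_len: int = DEFAULT_ST_CHECK_LEN
    anchor1: Optional[str] = None
    anchor1_offset: int = 0
    anchor2: Optional[str] = None
    anchor2_offset: int = 0
    anchor_window: int = 0

    def element_lengths(self) -> Dict[str, int]:
        return {name: length
                for name, _, length in (*self.read1_elements,
                                        *self.read2_elements)}


def layout_from_library(designs: Sequence[PegRNADesign],
                        st_check_len: int = DEFAULT_ST_CHECK_LEN,
                        anchor_scaffold: bool = False,
                        anchor_window: int = 0) -> CassetteLayout:
    """Derive the cassette layout from a library with uniform element lengths.

    Read 1 = spacer + scaffold + extension; read 2 = ST + pegRNA BC +
    library BC. With ``anchor_scaffold`` the (shared) scaffold sequence is
    used as an alignment anchor in read 1.
    """
    if not designs:
        raise SchemaError("empty library")
    lengths: Dict[str, set] = {}
    for d in designs:
        for name, attr in (("spacer", "spacer"), ("scaffold", "scaffold"),
                           ("extension", "extension"), ("st_read", "st_ref"),
                           ("pegrna_bc", "pegrna_bc"),
                           ("library_bc", "library_bc")):
            lengths.setdefault(name, set()).add(len(getattr(d, attr)))
    for name, ls in lengths.items():
        if len(ls) != 1:
            raise SchemaError(
                f"element {name!r} has non-uniform lengths {sorted(ls)}; "
                "a fixed-offset layout requires uniform element lengths"
            )
    L = {name: ls.pop() for name, ls in lengths.items()}
    read1 = []
    off = 0
    for name in ("spacer", "scaffold", "extension"):
        read1.append((name, off, L[name]))
        off += L[name]
    read2 = []
    off = 0
    for name in ("st_read", "pegrna_bc", "library_bc"):
        read2.append((name, off, L[name]))
        off += L[name]
    anchor1 = None
    anchor1_offset = 0
    if anchor_scaffold:
        scaffolds = {d.scaffold for d in designs}
        if len(scaffolds) != 1:
            raise SchemaError("anchor_scaffold requires a single shared scaffold")
        anchor1 = scaffolds.pop()
        anchor1_offset = L["spacer"]
    return CassetteLayout(read1, read2, st_check_len=st_check_len,
                          anchor1=anchor1, anchor1_offset=anchor1_offset,
                          anchor_window=anchor_window)


def _find_shift(read: str, anchor: str, offset: int, window: int) -> Optional[int]:
    # search shifts ordered by |shift| so the unshifted position wins ties
    for shift in sorted(range(-window, window + 1), key=abs):
        start = offset + shift
        if start < 0:
            continue
        if read[start:start + len(anchor)] == anchor:
            return shift
    return None


def extract_elements(read1: str, read2: str, layout: CassetteLayout):
    """Slice the six cassette elements out of a read pair.

    Returns an :class:`ElementSet`, or a :class:`Reject` with reason
    ``too_short`` or ``anchor_not_found``.
    """
    shift1 = shift2 = 0
    if layout.anchor1 is not None:
        s = _find_shift(read1, layout.anchor1, layout.anchor1_offset,
                        layout.anchor_window)
        if s is None:
            return Reject("anchor_not_found")
        shift1 = s
    if layout.anchor2 is not None:
        s = _find_shift(read2, layout.anchor2, layout.anchor2_offset,
                        layout.anchor_window)
        if s is None:
            return Reject("anchor_not_found")
        shift2 = s
    parts: Dict[str, str] = {}
    for read, elements, shift in ((read1, layout.read1_elements, shift1),
                                  (read2, layout.read2_elements, shift2)):
        for name, off, length in elements:
            start = off + shift
            end = start + length
            if start < 0 or end > len(read):
                return Reject("too_short")
            parts[name] = read[start:end]
    return ElementSet(**parts)


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length strings; N mismatches."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def match_element(seq: str, candidates: Dict[str, str],
                  mismatch_frac: float) -> Optional[str]:
    """Return the id of the unique nearest candidate within tolerance.

    Tolerance is ``floor(mismatch_frac * length)`` substitutions ("up to
    10%" read as an inclusive bound). A tie between two candidates at the
    minimal distance returns None: identity is never guessed.
    """
    best_id = None
    best_d = None
    tied = False
    for cid, cand in candidates.items():
        if len(cand) != len(seq):
            continue
        d = hamming(seq, cand)
        if best_d is None or d < best_d:
            best_id, best_d, tied = cid, d, False
        elif d == best_d:
            tied = True
    if best_d is None or tied:
        return None
    if best_d > int(np.floor(mismatch_frac * len(seq))):
        return None
    return best_id


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class ElementMatcher:
    """Vectorized per-element matching of reads against the library.

    For each element the distinct library sequences are the candidates; a
    confident match (distance within tolerance, unique minimizer among
    distinct sequences) yields the set of pegRNA ids sharing that sequence.
    The ST is represented only by its 3' suffix of ``layout.st_check_len`` nt.
    """

    def __init__(self, designs: Sequence[PegRNADesign],
                 layout: CassetteLayout, mismatch_frac: float = 0.10):
        self.layout = layout
        self.mismatch_frac = mismatch_frac
        attr_of = {"spacer": "spacer", "scaffold": "scaffold",
                   "extension": "extension", "st_read": "st_ref",
                   "pegrna_bc": "pegrna_bc", "library_bc": "library_bc"}
        self._tables: Dict[str, Tuple[np.ndarray, List[frozenset], int]] = {}
        for name in ELEMENT_NAMES:
            groups: Dict[str, set] = {}
            for d in designs:
                seq = getattr(d, attr_of[name])
                if name == "st_read":
                    seq = seq[-layout.st_check_len:]
                groups.setdefault(seq, set()).add(d.pegrna_id)
            seqs = sorted(groups)
            length = len(seqs[0])
            arr = np.stack([_encode(s) for s in seqs])
            idsets = [frozenset(groups[s]) for s in seqs]
            tol = int(np.floor(mismatch_frac * length))
            self._tables[name] = (arr, idsets, tol)

    def match(self, name: str, seq: str) -> Optional[frozenset]:
        arr, idsets, tol = self._tables[name]
        if name == "st_read":
            seq = seq[-self.layout.st_check_len:]
        if len(seq) != arr.shape[1]:
            return None
        q = _encode(seq)
        # N is always a mismatch, even against another N
        dists = (arr != q).sum(axis=1)
        if np.count_nonzero(q == ord("N")):
            dists = dists + ((arr == ord("N")) & (q == ord("N"))).sum(axis=1)
        i = int(np.argmin(dists))
        d = int(dists[i])
        if d > tol:
            return None
        if np.count_nonzero(dists == d) > 1:
            return None
        return idsets[i]


def classify_cassette(elements: ElementSet, matcher: ElementMatcher
                      ) -> Tuple[str, Optional[str]]:
    """Classify an element set as assigned / recombinant / unassigned.

    A read is ``assigned`` only when every element confidently matches and
    all matches agree on exactly one pegRNA; ``recombinant`` when two or more
    elements confidently match but no single pegRNA is consistent with all of
    them; ``unassigned`` otherwise.
    """
    matched: List[frozenset] = []
    n_total = 0
    for name in ELEMENT_NAMES:
        n_total += 1
        ids = matcher.match(name, getattr(elements, name))
        if ids is not None:
            matched.append(ids)
    if len(matched) < n_total:
        if len(matched) >= 2:
            inter = frozenset.intersection(*matched)
            if not inter:
                return "recombinant", None
        return "unassigned", None
    inter = frozenset.intersection(*matched)
    if not inter:
        return "recombinant", None
    if len(inter) == 1:
        return "assigned", next(iter(inter))
    return "unassigned", None


def count_and_quantify(assignments: Iterable[Tuple[str, str]],
                       designs: Sequence[PegRNADesign],
                       config: ScreenConfig,
                       sample_id: str = "") -> pd.DataFrame:
    """Tally assigned reads per pegRNA and quantify ST editing.

    ``assignments`` yields (pegrna_id, st_read) for assigned reads. An ST
    read is correctly edited iff it contains the design's intended edit plus
    its 5-nt flanks as an exact substring. The editing percentage is defined
    only for pegRNAs with at least ``config.min_st_reads`` ST reads.
    """
    core = {d.pegrna_id: d.st_edit_core for d in designs}
    counts: Counter = Counter()
    edited: Counter = Counter()
    for pid, st in assignments:
        if pid not in core:
            raise SchemaError(f"assigned pegrna_id {pid!r} not in library")
        counts[pid] += 1
        if core[pid] in st:
            edited[pid] += 1
    rows = []
    for d in designs:
        n = counts.get(d.pegrna_id, 0)
        k = edited.get(d.pegrna_id, 0)
        pct = 100.0 * k / n if n >= config.min_st_reads else np.nan
        rows.append((d.pegrna_id, sample_id, n, n, k, pct))
    return pd.DataFrame(rows, columns=["pegrna_id", "sample_id", "read_count",
                                       "st_total", "st_correct",
                                       "st_editing_pct"])


def process_sample(fastq_pairs: Iterable[Tuple[str, str, str]],
                   designs: Sequence[PegRNADesign],
                   config: ScreenConfig,
                   layout: Optional[CassetteLayout] = None,
                   sample_id: str = "") -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Run extraction, classification and quantification for one sample.

    Returns the per-pegRNA observation table and a tally of read fates
    (assigned / recombinant / unassigned / rejected); the four fates always
    sum to the number of input read pairs.
    """
    if layout is None:
        layout = layout_from_library(designs)
    matcher = ElementMatcher(designs, layout, config.element_mismatch_frac)
    stats = {"total": 0, "assigned": 0, "recombinant": 0,
             "unassigned": 0, "rejected": 0}
    assignments: List[Tuple[str, str]] = []
    for _rid, r1, r2 in fastq_pairs:
        stats["total"] += 1
        got = extract_elements(r1, r2, layout)
        if isinstance(got, Reject):
            stats["rejected"] += 1
            continue
        fate, pid = classify_cassette(got, matcher)
        stats[fate] += 1
        if fate == "assigned":
            assignments.append((pid, got.st_read))
    obs = count_and_quantify(assignments, designs, config, sample_id)
    logger.info(
        "sample %s: %d reads in, %d assigned, %d recombinant, "
        "%d unassigned, %d rejected",
        sample_id, stats["total"], stats["assigned"], stats["recombinant"],
        stats["unassigned"], stats["rejected"],
    )
    return obs, stats


def merge_replicates(observations: Sequence[pd.DataFrame],
                     config: ScreenConfig,
                     sample_id: str = "") -> pd.DataFrame:
    """Combine replicate observation tables of one condition/timepoint.

    Read and ST counts are summed across replicates; the editing percentage
    is the mean of the per-replicate defined percentages (not recomputed from
    pooled counts), so each replicate contributes equally.
    """
    if not observations:
        raise SchemaError("no observations to merge")
    merged = observations[0][["pegrna_id"]].copy()
    for col in ("read_count", "st_total", "st_correct"):
        merged[col] = sum(
            o.set_index("pegrna_id")[col].reindex(merged["pegrna_id"]).values
            for o in observations
        )
    pcts = pd.concat(
        [o.set_index("pegrna_id")["st_editing_pct"] for o in observations],
        axis=1,
    )
    merged["st_editing_pct"] = pcts.mean(axis=1, skipna=True).reindex(
        merged["pegrna_id"]).values
    merged.insert(1, "sample_id", sample_id)
    return merged


def negative_control_filter(control_obs: pd.DataFrame,
                            config: ScreenConfig) -> set:
    """pegRNAs with > ``neg_ctrl_editing_max_pct`` correct ST editing in the
    negative control are excluded (background from synthesis/sequencing
    error). Exactly at the threshold is retained. pegRNAs whose control
    editing is undefined (too few ST reads) are retained and logged.
    """
    pct = control_obs.set_index("pegrna_id")["st_editing_pct"]
    excluded = set(pct.index[pct > config.neg_ctrl_editing_max_pct])
    undefined = pct.index[pct.isna()]
    if len(undefined):
        logger.warning(
            "negative-control editing undefined for %d pegRNA(s) "
            "(st_total < %d); retained: %s",
            len(undefined), config.min_st_reads,
            ", ".join(map(str, undefined[:10])) + ("..." if len(undefined) > 10 else ""),
        )
    return excluded
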