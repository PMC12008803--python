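"""Domain types for pooled prime-editing screen analysis.

A screen assays a library of pegRNAs, each programming one genetic variant
and carrying a 55-nt surrogate target (ST) that reports the pegRNA's editing
activity, a 16-nt pegRNA barcode and a 10-nt library barcode. Samples are
grouped into conditions (cell line x co-selection); each condition has pre-
and post-selection timepoints plus a negative-control sample (library without
prime-editor expression) that defines background "editing".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

DNA_ALPHABET = frozenset("ACGTN")

CONSEQUENCES = frozenset(
    {
        "synonymous",
        "missense",
        "nonsense",
        "canonical_splice",
        "splice_region",
        "intronic",
        "utr5",
        "utr3",
        "upstream",
        "start_loss",
        "mnv",
        "deletion",
        "insertion",
    }
)

CLINVAR_CLASSES = frozenset(
    {"pathogenic_or_likely", "benign_or_likely", "vus", "none"}
)

SAMPLE_ROLES = frozenset({"pre", "post", "negative_control", "other"})

ST_LENGTH = 55
PEGRNA_BC_LENGTH = 16
LIBRARY_BC_LENGTH = 10
#: intended edit plus 5-nt flank on each side; a 1-nt edit gives an 11-nt core
MIN_EDIT_CORE_LENGTH = 11

FEATURE_NAMES = (
    "pbs_length",
    "rtt_length",
    "rtt_homology_length",
    "nick_to_edit_distance",
    "pbs_gc_fraction",
    "spacer_ontarget_score",
)


class SchemaError(ValueError):
    """A table or object violates the screen data model."""


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise SchemaError(f"{what}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SchemaError(f"{what}: non-DNA characters {sorted(bad)!r}")


@dataclass(frozen=True)
class PegRNADesign:
    """One library member: pegRNA elements plus its surrogate target.

    ``st_ref`` / ``st_edit_core`` are stored in the orientation in which the
    ST appears in read 2 (after any reverse-complementing done upstream);
    matching never guesses strand. ``st_edit_core`` is the intended edit
    flanked by exactly 5 nt on each side, in the same orientation.
    """

    pegrna_id: str
    variant_id: str
    spacer: str
    scaffold: str
    extension: str
    st_ref: str
    st_edit_core: str
    pegrna_bc: str
    library_bc: str
    features: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("spacer", "scaffold", "extension", "st_ref",
                     "st_edit_core", "pegrna_bc", "library_bc"):
            _check_dna(getattr(self, name), f"{self.pegrna_id}.{name}")
        if len(self.st_ref) != ST_LENGTH:
            raise SchemaError(
                f"{self.pegrna_id}: st_ref must be {ST_LENGTH} nt, "
                f"got {len(self.st_ref)}"
            )
        if len(self.pegrna_bc) != PEGRNA_BC_LENGTH:
            raise SchemaError(
                f"{self.pegrna_id}: pegrna_bc must be {PEGRNA_BC_LENGTH} nt"
            )
        if len(self.library_bc) != LIBRARY_BC_LENGTH:
            raise SchemaError(
                f"{self.pegrna_id}: library_bc must be {LIBRARY_BC_LENGTH} nt"
            )
        if len(self.st_edit_core) < MIN_EDIT_CORE_LENGTH:
            raise SchemaError(
                f"{self.pegrna_id}: st_edit_core must be at least "
                f"{MIN_EDIT_CORE_LENGTH} nt (edit plus 5-nt flanks)"
            )
        if self.st_edit_core in self.st_ref:
            raise SchemaError(
                f"{self.pegrna_id}: st_edit_core must differ from the "
                "corresponding window of st_ref"
            )


@dataclass(frozen=True)
class Variant:
    """The edit being assayed.

    ``variant_id`` is an opaque identifier (typically an HGVS string; never
    parsed). ``neutral_set``/``plof_set`` mark membership in the putatively
    neutral (pNeut) and putatively loss-of-function (pLoF) benchmark sets.
    """

    variant_id: str
    gene: str = ""
    genomic_pos: Optional[int] = None  # 1-based
    consequence: str = "missense"
    clinvar: str = "none"
    neutral_set: bool = False
    plof_set: bool = False

    def validate(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise SchemaError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if self.clinvar not in CLINVAR_CLASSES:
            raise SchemaError(
                f"{self.variant_id}: unknown clinvar class {self.clinvar!r}"
            )
        if self.neutral_set and self.plof_set:
            raise SchemaError(
                f"{self.variant_id}: cannot be in both neutral and pLoF sets"
            )


@dataclass(frozen=True)
class Sample:
    """One sequenced sample of a screen condition.

    ``screen_id`` identifies the condition (cell line x co-selection); the
    roles within one condition are pre-selection, post-selection and the
    negative control (library-transduced cells without prime editor).
    """

    sample_id: str
    screen_id: str
    cell_line: str
    coselection: bool
    timepoint: int
    replicate: int
    role: str

    def validate(self) -> None:
        if self.role not in SAMPLE_ROLES:
            raise SchemaError(f"{self.sample_id}: unknown role {self.role!r}")
        if self.timepoint < 0:
            raise SchemaError(f"{self.sample_id}: negative timepoint")


@dataclass
class ScreenConfig:
    """Analysis thresholds and mode switches for one screen.

    Defaults correspond to a negative-selection (essentiality-style) screen
    scored in a single condition: pegRNAs need a pre-selection frequency of
    at least 6e-5 and at least 75% correct ST editing; LoF is called at
    q < 0.05 against a normal null fitted to synonymous variants.
    """

    min_st_reads: int = 10
    neg_ctrl_editing_max_pct: float = 5.0
    element_mismatch_frac: float = 0.10
    freq_min: float = 6e-5
    st_activity_min_pct: float = 75.0
    q_cutoff: float = 0.05
    selection_direction: str = "depletion"  # or "enrichment"
    neutral_consequences: frozenset = frozenset({"synonymous"})
    plof_consequences: frozenset = frozenset({"nonsense", "canonical_splice"})
    et_ctrl_freq_max: float = 4e-4
    et_min_log2_gain: float = 1.0
    et_subtract_background: bool = True
    et_gain_filter: bool = False
    high_stringency_mean_st_pct: float = 36.0
    min_neutral: int = 5
    # "single": normalize pegRNA scores to the neutral median, then average
    # per variant (one-condition screens). "multi": per-condition function
    # scores, normalized, averaged across >=2 conditions, renormalized.
    scoring_mode: str = "single"
    two_sided: bool = False

    def validate(self) -> None:
        if self.selection_direction not in ("depletion", "enrichment"):
            raise SchemaError(
                f"unknown selection_direction {self.selection_direction!r}"
            )
        if self.scoring_mode not in ("single", "multi"):
            raise SchemaError(f"unknown scoring_mode {self.scoring_mode!r}")
        for name, lo, hi in (
            ("neg_ctrl_editing_max_pct", 0, 100),
            ("st_activity_min_pct", 0, 100),
            ("high_stringency_mean_st_pct", 0, 100),
            ("element_mismatch_frac", 0, 1),
            ("freq_min", 0, 1),
            ("q_cutoff", 0, 1),
            ("et_ctrl_freq_max", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise SchemaError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_st_reads < 1:
            raise SchemaError("min_st_reads must be >= 1")
        if self.min_neutral < 2:
            raise SchemaError("min_neutral must be >= 2")
        bad = (set(self.neutral_consequences) | set(self.plof_consequences)) \
            - CONSEQUENCES
        if bad:
            raise SchemaError(f"unknown consequences {sorted(bad)!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys {sorted(unknown)!r}")
        kwargs = dict(d)
        for key in ("neutral_consequences", "plof_consequences"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("neutral_consequences", "plof_consequences"):
            d[key] = sorted(d[key])
        return d


def variant_sets(
    variants,
    neutral_consequences=frozenset({"synonymous"}),
    plof_consequences=frozenset({"nonsense", "canonical_splice"}),
):
    """Return (neutral_ids, plof_ids) from a list of :class:`Variant`.

    Explicit set membership on the Variant takes precedence; otherwise
    membership is derived from the consequence class.
    """
    neutral, plof = set(), set()
    for v in variants:
        if v.neutral_set or (not v.plof_set and v.consequence in neutral_consequences):
            neutral.add(v.variant_id)
        elif v.plof_set or v.consequence in plof_consequences:
            plof.add(v.variant_id)
    return neutral, plof
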