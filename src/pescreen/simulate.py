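"""Synthetic pooled prime-editing screens with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* heterogeneous per-pegRNA editing, drawn from a two-component Beta mixture
  (an inactive and an active mode) so that editing rates are bimodal;
* accumulation of editing over culture time (geometric growth of the edited
  fraction, clamped at 1);
* selection acting multiplicatively on the *edited* subpopulation only —
  a LoF variant with effect ``s`` (doublings per unit selection time)
  multiplies its edited cells by ``2**(s * selection_time)``, while unedited
  carriers are neutral;
* per-pegRNA clonal drift shared between the cassette and endogenous-target
  readouts (both sequence the same cell population);
* lentiviral cassette recombination (ST + pegRNA-barcode block swapped with
  a random partner cassette), per-base substitution sequencing error, and a
  negative-control sample whose "editing" is background only.

Default class fractions emulate a saturation screen of essential coding
regions: 25% loss-of-function variants (|s| = 2), 15% intermediate
(|s| = 1), the rest neutral (s = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    LIBRARY_BC_LENGTH,
    PEGRNA_BC_LENGTH,
    ST_LENGTH,
    PegRNADesign,
    Sample,
    SchemaError,
    ScreenConfig,
    Variant,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

#: position of the programmed single-nucleotide edit within the 55-nt ST
EDIT_POS = 27


@dataclass
class SimParams:
    """Study conditions of the synthetic screen (all rates are fractions)."""

    seed: int
    n_variants: int = 200
    pegrnas_per_variant: int = 4
    max_pegrnas_per_variant: int = 9
    clamp_pegrnas: bool = False
    mixture_weights: Tuple[float, float] = (0.45, 0.55)  # inactive, active
    mixture_shapes: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (0.3, 3.0), (5.0, 1.5))
    recombination_frac: float = 0.02
    seq_error_rate: float = 0.001
    depth_per_sample: int = 500_000
    et_depth: int = 1_000_000
    growth: float = 1.05           # editing accumulation factor per day
    t_ref: int = 10                # day at which true_editing_rate applies
    selection_time: float = 3.0    # effective selection "doublings"
    fraction_lof: float = 0.25
    fraction_intermediate: float = 0.15
    lof_effect: float = 2.0
    intermediate_effect: float = 1.0
    selection_direction: str = "depletion"
    background_edit_rate: float = 0.001
    abundance_sigma: float = 0.5   # log2 SD of library skew
    growth_noise_sd: float = 0.2   # log2 SD of per-pegRNA clonal drift
    spacer_len: int = 20
    scaffold_len: int = 30
    extension_len: int = 25

    def validate(self) -> None:
        for name in ("recombination_frac", "seq_error_rate", "fraction_lof",
                     "fraction_intermediate", "background_edit_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SchemaError(f"{name}={v} outside [0, 1]")
        if self.fraction_lof + self.fraction_intermediate > 1:
            raise SchemaError("class fractions exceed 1")
        if self.n_variants < 1 or self.pegrnas_per_variant < 1:
            raise SchemaError("need at least one variant and one pegRNA")
        if self.depth_per_sample < 1:
            raise SchemaError("zero depth")
        if self.selection_direction not in ("depletion", "enrichment"):
            raise SchemaError(
                f"unknown selection_direction {self.selection_direction!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise SchemaError("seed is mandatory and must be an integer")


@dataclass
class SyntheticTruth:
    """Latent quantities behind a simulated screen.

    ``pegrna`` rows: pegrna_id, variant_id, true_editing_rate (edited
    fraction at day ``t_ref``), base_abundance. ``variant`` rows:
    variant_id, effect (s, doublings per unit selection time) and
    true_class in {lof, intermediate, neutral}.
    """

    pegrna: pd.DataFrame
    variant: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, length)]).decode()


def _unique_seqs(rng: np.random.Generator, n: int, length: int) -> List[str]:
    if 4 ** length < n:
        raise SchemaError(
            f"barcode space exhausted: need {n} distinct {length}-mers")
    seen: set = set()
    out: List[str] = []
    attempts = 0
    while len(out) < n:
        s = _random_seq(rng, length)
        attempts += 1
        if attempts > 100 * n + 1000:
            raise SchemaError("barcode space exhausted")
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def simulate_library(params: SimParams
                     ) -> Tuple[List[PegRNADesign], List[Variant],
                                SyntheticTruth]:
    """Generate a random library, variant annotations and their truth."""
    params.validate()
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_variants
    k = params.pegrnas_per_variant
    if k > params.max_pegrnas_per_variant:
        if params.clamp_pegrnas:
            k = params.max_pegrnas_per_variant
        else:
            raise SchemaError(
                f"pegrnas_per_variant={k} exceeds the cap of "
                f"{params.max_pegrnas_per_variant} (set clamp_pegrnas to clamp)"
            )

    n_lof = int(round(params.fraction_lof * n))
    n_int = int(round(params.fraction_intermediate * n))
    sign = -1.0 if params.selection_direction == "depletion" else 1.0
    classes: List[Tuple[str, str, float]] = []
    for i in range(n_lof):
        cons = "nonsense" if i % 3 != 2 else "canonical_splice"
        classes.append(("lof", cons, sign * params.lof_effect))
    for _ in range(n_int):
        classes.append(("intermediate", "missense",
                        sign * params.intermediate_effect))
    while len(classes) < n:
        classes.append(("neutral", "synonymous", 0.0))
    order = rng.permutation(n)

    library_bc = _random_seq(rng, LIBRARY_BC_LENGTH)
    pegrna_bcs = _unique_seqs(rng, n * k, PEGRNA_BC_LENGTH)
    scaffold = _random_seq(rng, params.scaffold_len)

    # per-pegRNA editing rates from the bimodal mixture
    comp = rng.random(n * k) < params.mixture_weights[1]
    (a0, b0), (a1, b1) = params.mixture_shapes
    e0 = np.where(comp, rng.beta(a1, b1, n * k), rng.beta(a0, b0, n * k))
    base = np.exp2(rng.normal(0.0, params.abundance_sigma, n * k))

    designs: List[PegRNADesign] = []
    variants: List[Variant] = []
    vrows, prows = [], []
    width = len(str(n))
    for vi in range(n):
        true_class, consequence, effect = classes[order[vi]]
        vid = f"var{vi + 1:0{width}d}"
        variants.append(Variant(
            variant_id=vid, gene="GENE1", genomic_pos=1000 + vi,
            consequence=consequence,
            neutral_set=(true_class == "neutral"),
            plof_set=(consequence in ("nonsense", "canonical_splice")),
        ))
        vrows.append((vid, effect, true_class))
        while True:
            st_ref = _random_seq(rng, ST_LENGTH)
            ref_base = st_ref[EDIT_POS]
            alt = "ACGT"[(_BASE_INDEX[ord(ref_base)] +
                          int(rng.integers(1, 4))) % 4]
            core = st_ref[EDIT_POS - 5:EDIT_POS] + alt \
                + st_ref[EDIT_POS + 1:EDIT_POS + 6]
            if core not in st_ref:
                break
        for j in range(k):
            gi = vi * k + j
            pid = f"{vid}_pg{j + 1}"
            features = {
                "pbs_length": float(rng.integers(8, 17)),
                "rtt_length": float(rng.integers(10, 35)),
                "rtt_homology_length": float(rng.integers(3, 25)),
                "nick_to_edit_distance": float(rng.integers(0, 20)),
                "pbs_gc_fraction": float(np.round(rng.random(), 3)),
                "spacer_ontarget_score": float(np.round(rng.random(), 3)),
            }
            designs.append(PegRNADesign(
                pegrna_id=pid, variant_id=vid,
                spacer=_random_seq(rng, params.spacer_len),
                scaffold=scaffold,
                extension=_random_seq(rng, params.extension_len),
                st_ref=st_ref, st_edit_core=core,
                pegrna_bc=pegrna_bcs[gi], library_bc=library_bc,
                features=features,
            ))
            prows.append((pid, vid, float(e0[gi]), float(base[gi])))

    truth = SyntheticTruth(
        pegrna=pd.DataFrame(prows, columns=["pegrna_id", "variant_id",
                                            "true_editing_rate",
                                            "base_abundance"]),
        variant=pd.DataFrame(vrows, columns=["variant_id", "effect",
                                             "true_class"]),
    )
    for d in designs:
        d.validate()
    return designs, variants, truth


def default_samples(screen_id: str = "screen1", cell_line: str = "HAP1-PE",
                    coselection: bool = False, t_pre: int = 10,
                    t_post: int = 34, n_replicates: int = 1) -> List[Sample]:
    """Pre/post/negative-control sample sheet for one condition. The
    negative control is harvested at the earliest timepoint."""
    samples = [Sample(f"{screen_id}_ctrl", screen_id, cell_line, coselection,
                      t_pre, 1, "negative_control")]
    for r in range(1, n_replicates + 1):
        samples.append(Sample(f"{screen_id}_pre_r{r}", screen_id, cell_line,
                              coselection, t_pre, r, "pre"))
        samples.append(Sample(f"{screen_id}_post_r{r}", screen_id, cell_line,
                              coselection, t_post, r, "post"))
    return samples


def _editing_at(e0: np.ndarray, t: float, params: SimParams) -> np.ndarray:
    return np.minimum(1.0, e0 * params.growth ** (t - params.t_ref))


def population_state(truth: SyntheticTruth, samples: Sequence[Sample],
                     params: SimParams) -> Dict[str, pd.DataFrame]:
    """Per-sample latent cell-population composition.

    For each sample: ``weight`` (relative abundance of each pegRNA's cell
    clone) and ``p_edit`` (edited fraction within the clone). Post-selection
    weights are ``base * [(1 - e) + e * 2**(s * selection_time)]`` times a
    shared clonal-drift factor; the drift stream is keyed to the sample
    index so cassette and ET readouts of the same sample agree.
    """
    tp = truth.pegrna
    effect = truth.variant.set_index("variant_id")["effect"]
    s = tp["variant_id"].map(effect).to_numpy(float)
    e0 = tp["true_editing_rate"].to_numpy(float)
    base = tp["base_abundance"].to_numpy(float)
    out: Dict[str, pd.DataFrame] = {}
    for idx, sample in enumerate(samples):
        if sample.role == "negative_control":
            weight = base.copy()
            p_edit = np.full_like(e0, params.background_edit_rate)
        elif sample.role == "pre":
            weight = base.copy()
            p_edit = _editing_at(e0, sample.timepoint, params)
        elif sample.role == "post":
            e_t = _editing_at(e0, sample.timepoint, params)
            sel = np.exp2(s * params.selection_time)
            f = (1.0 - e_t) + e_t * sel
            rng = np.random.default_rng([params.seed, 200 + idx])
            drift = np.exp2(rng.normal(0.0, params.growth_noise_sd, len(f)))
            weight = base * f * drift
            with np.errstate(invalid="ignore"):
                p_edit = np.where(f > 0, e_t * sel / f, 0.0)
        else:
            continue
        out[sample.sample_id] = pd.DataFrame({
            "pegrna_id": tp["pegrna_id"], "weight": weight, "p_edit": p_edit})
    return out


def simulate_counts(truth: SyntheticTruth, samples: Sequence[Sample],
                    params: SimParams) -> Dict[str, pd.DataFrame]:
    """Draw per-sample cassette counts and edited-ST counts.

    Counts are multinomial over pegRNAs at ``depth_per_sample``; edited STs
    are binomial within each pegRNA at its sample-specific edited fraction.
    """
    params.validate()
    state = population_state(truth, samples, params)
    out: Dict[str, pd.DataFrame] = {}
    for idx, sample in enumerate(samples):
        if sample.sample_id not in state:
            continue
        st = state[sample.sample_id]
        rng = np.random.default_rng([params.seed, 300 + idx])
        p = st["weight"].to_numpy() / st["weight"].sum()
        counts = rng.multinomial(params.depth_per_sample, p)
        edited = rng.binomial(counts, st["p_edit"].to_numpy())
        out[sample.sample_id] = pd.DataFrame({
            "pegrna_id": st["pegrna_id"], "sample_id": sample.sample_id,
            "count": counts, "edited": edited})
    return out


def observations_from_counts(counts: pd.DataFrame,
                             config: ScreenConfig) -> pd.DataFrame:
    """Convert a simulated count table into the observation-table layout."""
    n = counts["count"].to_numpy()
    k = counts["edited"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(n >= config.min_st_reads, 100.0 * k / np.maximum(n, 1),
                       np.nan)
    return pd.DataFrame({
        "pegrna_id": counts["pegrna_id"],
        "sample_id": counts["sample_id"],
        "read_count": n, "st_total": n, "st_correct": k,
        "st_editing_pct": pct,
    })


def _edited_st(design: PegRNADesign) -> str:
    """Reconstruct the fully edited ST by substituting the core into st_ref
    at the (unique) position where both 5-nt flanks match."""
    core = design.st_edit_core
    pos = design.st_ref.find(core[:5])
    while pos != -1:
        end = pos + len(core)
        if design.st_ref[end - 5:end] == core[-5:] and end <= len(design.st_ref):
            return design.st_ref[:pos] + core + design.st_ref[end:]
        pos = design.st_ref.find(core[:5], pos + 1)
    raise SchemaError(
        f"{design.pegrna_id}: cannot locate edit core flanks in st_ref")


def _apply_errors(mat: np.ndarray, rng: np.random.Generator,
                  rate: float) -> np.ndarray:
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    if not mask.any():
        return mat
    idx = _BASE_INDEX[mat[mask]]
    shift = rng.integers(1, 4, idx.shape)
    mat = mat.copy()
    mat[mask] = _BASES[(idx + shift) % 4]
    return mat


def simulate_screen(designs: Sequence[PegRNADesign], truth: SyntheticTruth,
                    samples: Sequence[Sample], params: SimParams,
                    outdir, compress: bool = True
                    ) -> Tuple[Dict[str, Tuple[str, str]],
                               Dict[str, pd.DataFrame]]:
    """Emit paired cassette FASTQ files per sample plus emitted-count truth.

    Each cassette copy carries an edited or unedited ST per the population
    state; with probability ``recombination_frac`` its ST + pegRNA-barcode
    block is swapped with a random partner cassette (emitted unedited);
    per-base substitution errors are applied last. Output is byte-identical
    for identical parameters and seed.
    """
    import os

    from .io import write_fastq, write_table

    os.makedirs(outdir, exist_ok=True)
    counts_by_sample = simulate_counts(truth, samples, params)
    read1_ref = np.stack([
        np.frombuffer((d.spacer + d.scaffold + d.extension).encode(),
                      dtype=np.uint8) for d in designs])
    read2_unedited = np.stack([
        np.frombuffer((d.st_ref + d.pegrna_bc + d.library_bc).encode(),
                      dtype=np.uint8) for d in designs])
    read2_edited = np.stack([
        np.frombuffer((_edited_st(d) + d.pegrna_bc + d.library_bc).encode(),
                      dtype=np.uint8) for d in designs])
    pid_index = {d.pegrna_id: i for i, d in enumerate(designs)}
    swap_len = ST_LENGTH + PEGRNA_BC_LENGTH

    fastq_paths: Dict[str, Tuple[str, str]] = {}
    emitted: Dict[str, pd.DataFrame] = {}
    ext = ".fastq.gz" if compress else ".fastq"
    for idx, sample in enumerate(samples):
        if sample.sample_id not in counts_by_sample:
            continue
        ctab = counts_by_sample[sample.sample_id]
        rng = np.random.default_rng([params.seed, 400 + idx])
        design_idx = np.repeat(
            [pid_index[p] for p in ctab["pegrna_id"]], ctab["count"])
        edited_flag = np.concatenate([
            np.arange(n) < k for n, k in zip(ctab["count"], ctab["edited"])
        ]) if len(design_idx) else np.zeros(0, dtype=bool)
        n_reads = len(design_idx)
        recomb = rng.random(n_reads) < params.recombination_frac
        partner = rng.integers(0, len(designs), n_reads)

        r1 = read1_ref[design_idx]
        r2 = np.where(edited_flag[:, None], read2_edited[design_idx],
                      read2_unedited[design_idx])
        if recomb.any():
            r2 = r2.copy()
            r2[recomb, :swap_len] = read2_unedited[partner[recomb], :swap_len]
        r1 = _apply_errors(r1, rng, params.seq_error_rate)
        r2 = _apply_errors(r2, rng, params.seq_error_rate)
        perm = rng.permutation(n_reads)

        p1 = os.path.join(outdir, f"{sample.sample_id}_R1{ext}")
        p2 = os.path.join(outdir, f"{sample.sample_id}_R2{ext}")
        ids = [f"{sample.sample_id}:{i}" for i in range(n_reads)]
        write_fastq(p1, ((ids[j], r1[perm[j]].tobytes().decode())
                         for j in range(n_reads)))
        write_fastq(p2, ((ids[j], r2[perm[j]].tobytes().decode())
                         for j in range(n_reads)))
        fastq_paths[sample.sample_id] = (p1, p2)

        etab = ctab.copy()
        recomb_per_design = np.bincount(design_idx[recomb],
                                        minlength=len(designs))
        lost_edited = np.bincount(design_idx[recomb & edited_flag],
                                  minlength=len(designs))
        order = [pid_index[p] for p in etab["pegrna_id"]]
        etab["n_recombined"] = recomb_per_design[order]
        etab["edited_emitted"] = (etab["edited"].to_numpy()
                                  - lost_edited[order])
        emitted[sample.sample_id] = etab
        write_table(etab, os.path.join(outdir,
                                       f"{sample.sample_id}_emitted.tsv"))
    return fastq_paths, emitted


def simulate_et_counts(designs: Sequence[PegRNADesign],
                       variants: Sequence[Variant], truth: SyntheticTruth,
                       samples: Sequence[Sample], params: SimParams
                       ) -> Dict[str, pd.DataFrame]:
    """Variant-level endogenous-target count tables per screen condition.

    Edited-allele abundance aggregates the same per-pegRNA population state
    used for cassette counts (shared clonal drift); a per-variant background
    frequency models sequencing error, with a small fraction of hotspot
    sites whose background exceeds the downstream exclusion threshold.
    Columns: ctrl (negative control), pre, post. A ``_wt`` row carries the
    unedited-allele counts so per-sample frequencies have their natural
    denominator (downstream analysis discards it as not programmed).
    """
    params.validate()
    state = population_state(truth, samples, params)
    tp = truth.pegrna
    vids = [v.variant_id for v in variants]
    v_index = {v: i for i, v in enumerate(vids)}
    peg_v = np.array([v_index[v] for v in tp["variant_id"]])

    bg_rng = np.random.default_rng([params.seed, 7])
    background = bg_rng.exponential(3e-5, len(vids))
    hot = bg_rng.random(len(vids)) < 0.03
    background[hot] = bg_rng.uniform(2e-4, 1e-3, int(hot.sum()))

    screens = sorted({s.screen_id for s in samples})
    out: Dict[str, pd.DataFrame] = {}
    for sidx, screen_id in enumerate(screens):
        cols = {}
        rng = np.random.default_rng([params.seed, 600 + sidx])
        for role, col in (("negative_control", "ctrl"), ("pre", "pre"),
                          ("post", "post")):
            sub = [s for s in samples
                   if s.screen_id == screen_id and s.role == role]
            if not sub:
                raise SchemaError(f"screen {screen_id!r} lacks a {role} sample")
            sample = sub[0]
            st = state[sample.sample_id]
            w = st["weight"].to_numpy()
            edited_w = w * st["p_edit"].to_numpy()
            total = w.sum()
            freq = np.bincount(peg_v, weights=edited_w,
                               minlength=len(vids)) / total
            if role == "negative_control":
                p = background.copy()
            else:
                p = freq + background
            p = np.append(p, max(0.0, 1.0 - p.sum()))  # wildtype remainder
            p = p / p.sum()
            cols[col] = rng.multinomial(params.et_depth, p)
        out[screen_id] = pd.DataFrame(
            cols, index=pd.Index(vids + ["_wt"], name="variant_id"))
    return out
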