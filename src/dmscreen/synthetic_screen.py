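"""Synthetic selection screens with known ground truth.

The simulator emulates a pooled ORF-variant survival screen: library
representation is log-normal with a configurable dropout tail, selection is
one deterministic proportional-growth step under a rule-based fitness model
(loss-of-function variants survive the cytotoxic drug, functional variants
are killed down to a small residual; the DMSO and trequinsin arms are
neutral), and sequencing is a multinomial draw per sample.  Optionally the
counts are rendered into paired FASTQ reads with uniform substitution
errors.  Every stage flows from a single seeded generator, so all artifacts
are reproducible from (config, seed).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .library_design import LibraryDesign, VariantSpec
from .read_deconvolution import CountsMatrix
from .selection_scoring import SampleSheet
from .sequence_core import (
    CODONS_FOR_AA,
    ORFSequence,
    RestrictionSite,
    find_restriction_sites,
    reverse_complement,
)

__all__ = [
    "FitnessModel",
    "ScreenSimConfig",
    "random_orf",
    "simulate_representation",
    "apply_selection",
    "simulate_counts",
    "simulate_screen",
    "simulate_reads",
    "evaluate_hits",
]

#: Number of C-terminal codons where a premature stop no longer abolishes
#: function (truncations within this tail still support drug response).
FUNCTIONAL_STOP_TAIL = 59

DNMDP_CONDITIONS = ("DNMDP10", "DNMDP100")


def random_orf(
    n_codons: int,
    seed: int | np.random.Generator,
    id: str = "synthetic_orf",
    codon_offset: int = 1,
    avoid_sites: tuple[RestrictionSite, ...] = (),
) -> ORFSequence:
    """A random stop-free ORF, optionally avoiding given restriction sites."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sense = sorted(c for aa, cs in CODONS_FOR_AA.items() if aa != "*" for c in cs)
    pad = max((len(s.recognition) for s in avoid_sites), default=1) - 1
    codons: list[str] = []
    for _ in range(n_codons):
        for _attempt in range(100):
            cand = sense[rng.integers(len(sense))]
            tail = "".join(codons[-(pad // 3 + 1):]) + cand
            if not any(find_restriction_sites(tail, s) for s in avoid_sites):
                break
        else:
            raise RuntimeError("could not avoid forbidden sites")
        codons.append(cand)
    return ORFSequence(id, "".join(codons), codon_offset)


@dataclass(frozen=True)
class FitnessModel:
    """Rule-based survival weights per condition.

    A variant is loss-of-function (and therefore drug-resistant) if it is a
    nonsense variant outside the functional C-terminal tail, or if it is in
    the programmed resistance set of (codon_number, alt_aa) pairs.  Under
    the cytotoxic-drug arms, loss-of-function variants keep weight 1 and
    functional variants (including wild-type and silent alleles) survive
    only at ``delta``; every variant has weight 1 at T0 and under the DMSO
    and trequinsin arms.
    """

    delta: float = 0.05
    programmed_resistance: frozenset[tuple[int, str]] = frozenset()
    functional_stop_tail: int = FUNCTIONAL_STOP_TAIL

    def __post_init__(self) -> None:
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        object.__setattr__(
            self, "programmed_resistance", frozenset(self.programmed_resistance)
        )

    def loss_of_function(self, spec: VariantSpec, orf_last_codon: int) -> bool:
        if spec.var_class == "nonsense":
            return spec.codon_number <= orf_last_codon - self.functional_stop_tail
        return (spec.codon_number, spec.alt_aa) in self.programmed_resistance

    def weight(self, spec: VariantSpec | None, condition: str, orf_last_codon: int) -> float:
        if condition not in DNMDP_CONDITIONS:
            return 1.0
        if spec is not None and self.loss_of_function(spec, orf_last_codon):
            return 1.0
        return self.delta  # functional allele (or WT carrier): killed by drug


@dataclass(frozen=True)
class ScreenSimConfig:
    """Study conditions of the simulated screen."""

    depth: int = 1_000_000
    replicates: int = 2
    representation_sigma: float = 1.0
    dropout_fraction: float = 0.05
    wt_fraction: float = 0.01
    error_rate: float = 0.0
    read_length: int = 150
    seed: int = 0
    conditions: tuple[str, ...] = ("DMSO", "DNMDP10", "DNMDP100", "TREQ100")

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error rate must be in [0, 0.05]")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")


def simulate_representation(
    design: LibraryDesign, config: ScreenSimConfig, rng: np.random.Generator
) -> pd.Series:
    """T0 abundances: i.i.d. log-normal per variant, a dropout tail at
    near-zero abundance, plus a WT carrier; sums to 1."""
    ids = [v.variant_id for v in design.variants]
    n = len(ids)
    if n == 0:
        raise ValueError("empty design")
    raw = rng.lognormal(mean=0.0, sigma=config.representation_sigma, size=n)
    n_drop = int(round(config.dropout_fraction * n))
    if n_drop:
        drop_idx = rng.choice(n, size=n_drop, replace=False)
        raw[drop_idx] *= 1e-4
    raw = raw / raw.sum() * (1.0 - config.wt_fraction)
    ab = pd.Series(raw, index=ids)
    ab["WT"] = config.wt_fraction
    return ab / ab.sum()


def apply_selection(
    abundances: pd.Series,
    fitness: FitnessModel,
    condition: str,
    design: LibraryDesign,
) -> pd.Series:
    """One proportional-growth step: abundance x weight, renormalized."""
    specs = design.by_id()
    last = design.reference.last_codon
    weights = pd.Series(
        {
            vid: fitness.weight(specs.get(vid), condition, last)
            for vid in abundances.index
        }
    )
    post = abundances * weights
    return post / post.sum()


def simulate_counts(
    abundances: pd.Series, depth: int, rng: np.random.Generator
) -> pd.Series:
    """One multinomial draw of ``depth`` reads over the abundance vector."""
    p = abundances.to_numpy(dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("abundances must sum to 1")
    counts = rng.multinomial(depth, p / p.sum())
    return pd.Series(counts, index=abundances.index)


def simulate_screen(
    design: LibraryDesign,
    config: ScreenSimConfig,
    fitness: FitnessModel = FitnessModel(),
) -> tuple[CountsMatrix, pd.DataFrame, SampleSheet]:
    """Simulate a full screen: counts matrix, truth table, sample sheet.

    Samples are T0 plus each configured arm, with ``replicates`` independent
    multinomial draws each; abundances at T0 are shared across replicates
    (one infection, split after puromycin selection).
    """
    rng = np.random.default_rng(config.seed)
    t0_ab = simulate_representation(design, config, rng)
    specs = design.by_id()
    last = design.reference.last_codon

    truth = pd.DataFrame(index=t0_ab.index)
    truth.index.name = "variant_id"
    truth["t0_abundance"] = t0_ab
    truth["loss_of_function"] = [
        fitness.loss_of_function(specs[v], last) if v in specs else False
        for v in truth.index
    ]

    post = {"T0": t0_ab}
    for cond in config.conditions:
        post[cond] = apply_selection(t0_ab, fitness, cond, design)
        truth[f"expected_{cond.lower()}"] = post[cond]

    rows, samples = [], {}
    for cond in ("T0",) + tuple(config.conditions):
        for rep in range(1, config.replicates + 1):
            sid = f"{cond}_r{rep}"
            samples[sid] = simulate_counts(post[cond], config.depth, rng)
            rows.append({"sample_id": sid, "condition": cond, "replicate": rep})
    sheet = SampleSheet(pd.DataFrame(rows))

    variant_ids = [v.variant_id for v in design.variants]
    mat = CountsMatrix.empty(variant_ids, list(samples))
    for sid, cnt in samples.items():
        mat.counts.loc[cnt.index, sid] = cnt.to_numpy()
    return CountsMatrix(mat.counts, mat.counts.sum(axis=0)), truth, sheet


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        bases = np.array([b"A", b"C", b"G", b"T"])
        for i in np.flatnonzero(hit):
            choices = bases[bases != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_reads(
    design: LibraryDesign,
    counts_per_sample: dict[str, pd.Series],
    config: ScreenSimConfig,
    out_dir,
    gz: bool = False,
    min_overlap: int = 40,
    cover_variant: bool = True,
) -> dict[str, tuple[Path, Path]]:
    """Render per-sample counts into paired FASTQ files.

    For each counted variant, that many read pairs are drawn from random
    fragments of the variant's full-length sequence (by default constrained
    to cover the edited codon, so that error-free reads reproduce the input
    counts exactly); substitution errors are applied at the configured rate
    with flat Q37 quality strings.  Reads for the WT row come from the
    reference.  Byte-identical across runs for the same config and seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = design.reference
    amplicon_len = len(ref.nucleotides)
    L = config.read_length
    if L > amplicon_len:
        raise ValueError("read length exceeds amplicon length")
    frag_len = min(amplicon_len, 2 * L - min_overlap)
    specs = design.by_id()
    paths: dict[str, tuple[Path, Path]] = {}
    suffix = ".fastq.gz" if gz else ".fastq"
    for sample, counts in counts_per_sample.items():
        p1 = out_dir / f"{sample}_R1{suffix}"
        p2 = out_dir / f"{sample}_R2{suffix}"
        opener = gzip.open if gz else open
        with opener(p1, "wt") as f1, opener(p2, "wt") as f2:
            serial = 0
            for vid in counts.index:
                c = int(counts[vid])
                if c == 0:
                    continue
                if vid in specs:
                    spec = specs[vid]
                    full = design.variant_sequence(spec)
                    ci = (spec.codon_number - ref.codon_offset) * 3
                elif vid == "WT":
                    full, ci = ref.nucleotides, None
                else:
                    continue  # reserved junk rows carry no sequence
                lo, hi = 0, amplicon_len - frag_len
                if cover_variant and ci is not None:
                    lo = max(0, ci + 3 - frag_len)
                    hi = min(ci, amplicon_len - frag_len)
                starts = rng.integers(lo, hi + 1, size=c)
                for s in starts:
                    frag = full[s : s + frag_len]
                    r1 = _apply_errors(frag[:L], config.error_rate, rng)
                    r2 = _apply_errors(
                        reverse_complement(frag)[:L], config.error_rate, rng
                    )
                    serial += 1
                    name = f"{sample}:{serial}"
                    q = "F" * L
                    f1.write(f"@{name}/1\n{r1}\n+\n{q}\n")
                    f2.write(f"@{name}/2\n{r2}\n+\n{q}\n")
        paths[sample] = (p1, p2)
    return paths


def evaluate_hits(
    score_table: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of hit calls against the
    simulator's truth, over retained (non-low-confidence) variants."""
    retained = score_table[~score_table["low_confidence"]]
    lof = truth["loss_of_function"].reindex(retained.index).fillna(False)
    called = retained["resistance_hit"].fillna(False).astype(bool)
    tp = int((called & lof).sum())
    fp = int((called & ~lof).sum())
    fn = int((~called & lof).sum())
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    fdp = fp / (tp + fp) if tp + fp else 0.0
    return {
        "sensitivity": sensitivity,
        "fdp": fdp,
        "n_hits": tp + fp,
        "n_lof_retained": tp + fn,
    }
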