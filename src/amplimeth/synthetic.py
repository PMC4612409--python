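"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the structure of the study's inputs: stage-labelled
log2 expression matrices (normal/adenoma/CRC groups), 454-style bisulfite
amplicon reads with homopolymer-inflated indel errors, multi-plate miRNA qPCR
Ct panels with interplate calibrators and the miR-423-5p reference, and
TMA-core Q-score tables.  Every generator is deterministic given its seed and
records what it planted in a :class:`SyntheticTruth` so downstream recovery
can be measured.

Seed policy for the read simulator: three independent child streams are
derived as ``default_rng([seed, k])`` with k = 0 (methylation draws),
1 (conversion draws), 2 (sequencing errors).  The methylation stream draws
one uniform vector per read (one value per CpG site), so the per-site
methylated-read counts recorded in the truth can be reproduced by any sampler
replaying stream 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .align import AmpliconTemplate
from .mirna import CALIBRATOR_ID, MAX_CYCLE, REFERENCE_MIRNA, CtPlateSet
from .trends import ExpressionMatrix

__all__ = [
    "SyntheticTruth",
    "gen_staged_expression",
    "gen_bisulfite_reads",
    "gen_ct_plates",
    "gen_qscore_cores",
    "default_template",
]

STAGES = ("normal", "adenoma", "CRC")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators (fields unused by a generator
    stay at their empty defaults)."""

    trend_genes: dict[str, str] = field(default_factory=dict)  # gene -> up/down
    cpg_methylation: list[float] = field(default_factory=list)
    cpg_methylated_draws: list[int] = field(default_factory=list)
    n_reads: int = 0
    differential_mirnas: dict[str, dict[str, float]] = field(default_factory=dict)
    group_assignments: dict[str, str] = field(default_factory=dict)
    plate_offsets: dict[str, float] = field(default_factory=dict)
    qscore_group_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.cpg_methylation):
            raise ValueError("methylation probabilities must lie in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def gen_staged_expression(
    n_genes: int = 1000,
    n_per_group: int = 10,
    n_trend_up: int = 25,
    n_trend_down: int = 25,
    step_effect: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    context: str = "biopsy",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Stage-labelled log2 expression matrix with planted monotone trends.

    Planted genes step by ``step_effect`` log2 units per stage (baseline,
    baseline ± step, baseline ± 2·step for normal, adenoma, CRC); null genes
    keep one mean across stages.  Gaussian noise with SD ``noise_sd`` is added
    everywhere.  Per-gene baselines are uniform on [3, 12] log2 units, the
    intensity range of the study's arrays.
    """
    if n_genes < 1 or n_per_group < 1:
        raise ValueError("n_genes and n_per_group must be positive")
    if n_trend_up < 0 or n_trend_down < 0 or n_trend_up + n_trend_down > n_genes:
        raise ValueError("planted counts must be ≥ 0 and sum to ≤ n_genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    prefixes = {"normal": "N", "adenoma": "AD", "CRC": "CRC"}
    samples, stages = [], []
    for stage in STAGES:
        for i in range(n_per_group):
            samples.append(f"{prefixes[stage]}{i + 1:03d}")
            stages.append(stage)
    baseline = rng.uniform(3.0, 12.0, size=n_genes)
    direction = np.zeros(n_genes)
    direction[:n_trend_up] = 1.0
    direction[n_trend_up : n_trend_up + n_trend_down] = -1.0
    stage_code = np.repeat([0, 1, 2], n_per_group)
    means = baseline[:, None] + direction[:, None] * step_effect * stage_code[None, :]
    values = means + rng.normal(0.0, noise_sd, size=means.shape)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.DataFrame({"stage": stages, "context": context}, index=samples),
    )
    truth = SyntheticTruth(
        trend_genes={
            g: ("up" if d > 0 else "down")
            for g, d in zip(genes, direction)
            if d != 0
        },
        group_assignments=dict(zip(samples, stages)),
    )
    return matrix, truth


#: a 120-nt synthetic promoter-like amplicon with three CpG sites, used as the
#: default template for simulated bisulfite runs
_DEFAULT_AMPLICON = (
    "ACCTAGGTTT" "GAGTTACAGT" "TCGTTAGGTT" "AGGATTTCAT"
    "TAGCGTTTAG" "GACTTAGGTA" "GTTAGGACTT" "AGGTTTAGGA"
    "GTTACGTTAG" "GAGTTTACTA" "TAGGAGTTAG" "GACTTAGGTT"
)


def default_template(name: str = "sim_amplicon") -> AmpliconTemplate:
    """The built-in 3-CpG amplicon template used by simulations."""
    return AmpliconTemplate(name=name, seq=_DEFAULT_AMPLICON)


def _mutate(seq: list[str], rng, sub_rate, indel_rate, homopolymer_multiplier):
    """Apply substitution and indel errors; indel rate is multiplied inside
    homopolymer runs of length ≥ 3 (454-style error model)."""
    n = len(seq)
    # run length at each position, computed on the converted sequence
    in_run = [False] * n
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 3:
            for k in range(i, j):
                in_run[k] = True
        i = j
    bases = "ACGT"
    sub_draw = rng.random(n)
    indel_draw = rng.random(n)
    ins_or_del = rng.random(n)
    sub_choice = rng.integers(0, 3, size=n)
    out: list[str] = []
    for k, b in enumerate(seq):
        ind_rate = indel_rate * (homopolymer_multiplier if in_run[k] else 1.0)
        if sub_draw[k] < sub_rate:
            b = bases.replace(b, "")[sub_choice[k]] if b in bases else b
        if indel_draw[k] < ind_rate:
            if ins_or_del[k] < 0.5:
                out.append(b)  # insertion: duplicate the base
                out.append(b)
            # deletion: emit nothing
        else:
            out.append(b)
    return out


def gen_bisulfite_reads(
    template: AmpliconTemplate,
    methylation,
    n_reads: int = 500,
    conversion_efficiency: float = 1.0,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    homopolymer_multiplier: float = 3.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Simulate bisulfite-converted forward-strand reads of one amplicon.

    Per read, each CpG cytosine stays C with its site's methylation
    probability (else T); every other cytosine converts to T with probability
    ``conversion_efficiency``; substitutions then indels are applied per base,
    the indel rate inflated by ``homopolymer_multiplier`` inside runs of ≥ 3
    identical bases.  Reads are full amplicon length before errors (amplicon
    sequencing, no fragmentation).
    """
    methylation = np.asarray(methylation, dtype=float)
    cpg = template.cpg_positions
    if methylation.shape != (len(cpg),):
        raise ValueError(
            f"methylation vector length {methylation.shape} does not match "
            f"the template's {len(cpg)} CpG sites"
        )
    for name, val in (
        ("conversion_efficiency", conversion_efficiency),
        ("sub_rate", sub_rate),
        ("indel_rate", indel_rate),
    ):
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if homopolymer_multiplier < 1:
        raise ValueError("homopolymer_multiplier must be ≥ 1")
    if n_reads < 1:
        raise ValueError("n_reads must be positive")
    if (np.any(methylation < 0)) or (np.any(methylation > 1)):
        raise ValueError("methylation probabilities must lie in [0, 1]")

    meth_rng = np.random.default_rng([seed, 0])
    conv_rng = np.random.default_rng([seed, 1])
    err_rng = np.random.default_rng([seed, 2])
    cpg_set = set(cpg)
    draws = np.zeros(len(cpg), dtype=int)
    reads: list[tuple[str, str]] = []
    seq = template.seq
    non_cpg_c = [i for i, b in enumerate(seq) if b == "C" and i not in cpg_set]
    for r in range(n_reads):
        meth_state = meth_rng.random(len(cpg)) < methylation
        draws += meth_state
        conv_state = conv_rng.random(len(non_cpg_c)) < conversion_efficiency
        out = list(seq)
        for s, p in enumerate(cpg):
            out[p] = "C" if meth_state[s] else "T"
        for c, p in enumerate(non_cpg_c):
            if conv_state[c]:
                out[p] = "T"
        if sub_rate > 0 or indel_rate > 0:
            out = _mutate(out, err_rng, sub_rate, indel_rate,
                          homopolymer_multiplier)
        reads.append((f"{template.name}_read{r:05d}", "".join(out)))
    truth = SyntheticTruth(
        cpg_methylation=[float(p) for p in methylation],
        cpg_methylated_draws=[int(d) for d in draws],
        n_reads=n_reads,
    )
    return reads, truth


def gen_ct_plates(
    n_mirnas: int = 40,
    groups: dict[str, int] | None = None,
    plate_offsets=(0.0, 1.5),
    planted_shifts: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[CtPlateSet, SyntheticTruth]:
    """Multi-plate raw Ct panel with plate offsets and planted group shifts.

    Raw Ct = per-miRNA base + the plate's offset + the miRNA's planted shift
    for the sample's group + Gaussian noise.  miRNAs are split across the
    plates (panel-style); every plate carries one interplate-calibrator well
    holding base 20 + the plate offset.  The reference miRNA must not carry a
    planted shift.
    """
    groups = groups or {"NAT": 3, "AD": 3, "CRC": 3}
    planted_shifts = planted_shifts or {}
    if REFERENCE_MIRNA in planted_shifts:
        raise ValueError("the reference miRNA cannot carry a planted shift")
    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    planted_ids = sorted(planted_shifts)
    n_fill = n_mirnas - len(planted_ids) - 1
    if n_fill < 0:
        raise ValueError("n_mirnas too small for the planted set + reference")
    mirnas = planted_ids + [REFERENCE_MIRNA] + [
        f"miR-sim-{i + 1:03d}" for i in range(n_fill)
    ]
    rng = np.random.default_rng(seed)
    base = dict(zip(mirnas, rng.uniform(24.0, 34.0, size=len(mirnas))))
    base[REFERENCE_MIRNA] = 28.0  # stable housekeeping level
    plates = [f"plate_{i + 1}" for i in range(len(plate_offsets))]
    plate_of = {
        m: plates[i * len(plates) // len(mirnas)] for i, m in enumerate(mirnas)
    }
    offset = dict(zip(plates, plate_offsets))
    samples, labels = [], {}
    for g, n in groups.items():
        for i in range(n):
            s = f"{g}{i + 1:02d}"
            samples.append(s)
            labels[s] = g
    rows = []
    for p in plates:
        rows.append({
            "mirna": CALIBRATOR_ID, "sample": "calibrator", "plate": p,
            "ct": 20.0 + offset[p], "is_calibrator": True,
        })
    for m in mirnas:
        for s in samples:
            shift = planted_shifts.get(m, {}).get(labels[s], 0.0)
            ct = base[m] + offset[plate_of[m]] + shift
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            rows.append({
                "mirna": m, "sample": s, "plate": plate_of[m],
                "ct": float(np.clip(ct, 1.0, MAX_CYCLE)),
                "is_calibrator": False,
            })
    plate_set = CtPlateSet(pd.DataFrame(rows))
    truth = SyntheticTruth(
        differential_mirnas={m: dict(v) for m, v in planted_shifts.items()},
        group_assignments=labels,
        plate_offsets=offset,
    )
    return plate_set, truth


def gen_qscore_cores(
    group_means: dict[str, float] | None = None,
    n_cores: int = 10,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """TMA core table whose per-group Q-score means track ``group_means``.

    Intensity is the smallest value in {1, 2, 3} that can realize the mean
    (⌈mean/100⌉, 0 for a zero mean); percent positive is mean/intensity plus
    Gaussian noise, clipped to [0, 100].
    """
    group_means = group_means or {"NAT": 240.0, "AD": 140.0, "CRC": 60.0}
    for g, m in group_means.items():
        if not 0 <= m <= 300:
            raise ValueError(f"group mean for {g} outside [0, 300]")
    if n_cores < 1:
        raise ValueError("n_cores must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for g, m in group_means.items():
        intensity = 0 if m == 0 else int(np.ceil(m / 100.0))
        target_pct = 0.0 if intensity == 0 else m / intensity
        for i in range(n_cores):
            pct = target_pct
            if noise_sd > 0:
                pct += rng.normal(0.0, noise_sd)
            pct = float(np.clip(pct, 0.0, 100.0))
            rows.append({
                "core_id": f"{g}_core{i + 1:02d}",
                "group": g,
                "percent_positive": pct,
                "intensity": intensity,
            })
    return pd.DataFrame(rows)
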