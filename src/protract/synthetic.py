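"""Seeded synthetic inputs with recorded ground truth for every stage.

Real inputs for this pipeline (a curated proteome, blot densitometry,
gradient traces) cannot be bundled, so each generator emulates the
structure of the corresponding assay and records the planted truth so
recovery can be asserted exactly:

* :func:`gen_proteome` — a two-class proteome (gene set vs background)
  in which poly-proline tracts are planted explicitly and background
  residues can never form an accidental tract at the scan threshold;
* :func:`gen_trace` — an absorbance trace that is a sum of Gaussian
  peaks (40S, 60S, 80S, polysome series) on a linear baseline with
  additive Gaussian noise scaled to the 80S peak height;
* :func:`gen_blot` — lane signals that are true group means under
  multiplicative lognormal lane-loading and measurement noise, with a
  loading-control channel sharing the same lane loading;
* :func:`gen_ct_table` — qPCR CT pairs consistent with chosen true
  relative expression levels.

Every generator is a pure function of its spec (seed included):
identical specs give identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from protract.polysome import Trace
from protract.ppt_scan import GeneSet, PPTProfile
from protract.quant import BlotTable

#: the 19 proteinogenic amino acids other than proline
NON_PROLINE = "ACDEFGHIKLMNQRSTVWY"


# ---------------------------------------------------------------------------
# proteome


@dataclass(frozen=True)
class ProteomeSpec:
    """Two-class proteome with planted poly-proline tracts.

    Defaults mirror the scale of the human analysis this emulates: a
    685-gene set against a 17981-gene background, with carrier
    probabilities near the observed 28.9% and 24.2%. Tract lengths
    follow ``min_tract_len + (geometric(tract_len_q) - 1)``, giving a
    heavy right tail (longest tracts around 9+ at the defaults).
    """

    n_set: int = 685
    n_background: int = 17981
    p_ppt_set: float = 0.289
    p_ppt_background: float = 0.242
    tract_count_mean: float = 0.7   # mean extra tracts (Poisson) given carrier
    tract_len_q: float = 0.55       # geometric success prob for length law
    min_tract_len: int = 3
    seq_len_range: tuple[int, int] = (120, 600)
    p_isolated_proline: float = 0.02  # per-residue chance of a sub-threshold P
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ppt_set", "p_ppt_background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seq_len_range[0] < 30:
            raise ValueError("sequences must be at least 30 residues")
        if not 0 < self.tract_len_q <= 1:
            raise ValueError("tract_len_q must be in (0, 1]")
        if self.min_tract_len < 2:
            raise ValueError("min_tract_len must be >= 2")


@dataclass(frozen=True)
class SyntheticProteome:
    """Generated records plus the planted-tract truth table."""

    spec: ProteomeSpec
    records: tuple[tuple[str, str], ...]        # (protein_id, sequence)
    truth: pd.DataFrame                         # protein_id, class, seq_length, start, length
    gene_set: GeneSet

    def truth_profiles(self) -> list[PPTProfile]:
        """Expected scan output computed from the planted truth alone."""
        by_id = {pid: [] for pid, _ in self.records}
        lengths = {pid: len(seq) for pid, seq in self.records}
        for row in self.truth.itertuples():
            if row.length > 0:
                by_id[row.protein_id].append(row.length)
        return [
            PPTProfile(
                protein_id=pid,
                seq_length=lengths[pid],
                n_tracts=len(tracts),
                longest_tract=max(tracts, default=0),
                total_prolines=sum(tracts),
            )
            for pid, tracts in by_id.items()
        ]

    def write(self, fasta_path: str | Path, truth_path: str | Path | None = None) -> None:
        with open(fasta_path, "w") as fh:
            for pid, seq in self.records:
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _gap(rng: np.random.Generator, length: int, spec: ProteomeSpec) -> str:
    """Non-tract filler: non-proline letters plus isolated sub-threshold prolines.

    The first and last residue are always non-proline so the gap can
    never extend an adjacent planted tract; interior prolines are spaced
    so no run reaches ``min_tract_len``.
    """
    if length == 0:
        return ""
    letters = list(rng.choice(list(NON_PROLINE), size=length))
    if length > 2 and spec.p_isolated_proline > 0:
        n_iso = rng.binomial(length, spec.p_isolated_proline)
        positions = np.sort(rng.choice(np.arange(1, length - 1), size=min(n_iso, length - 2),
                                       replace=False))
        last = -spec.min_tract_len
        for pos in positions:
            if pos - last >= spec.min_tract_len:
                letters[pos] = "P"
                last = pos
    return "".join(letters)


def _one_sequence(
    rng: np.random.Generator, carrier: bool, spec: ProteomeSpec
) -> tuple[str, list[tuple[int, int]]]:
    """Build one sequence and the list of (start, length) planted tracts."""
    seq_len = int(rng.integers(spec.seq_len_range[0], spec.seq_len_range[1] + 1))
    if not carrier:
        return _gap(rng, seq_len, spec), []
    n_tracts = 1 + rng.poisson(spec.tract_count_mean)
    lengths = [
        spec.min_tract_len + int(rng.geometric(spec.tract_len_q)) - 1
        for _ in range(n_tracts)
    ]
    # shed tracts (never below one) until they fit with >=1 residue gaps
    while lengths and sum(lengths) + (len(lengths) + 1) > seq_len:
        if len(lengths) == 1:
            raise ValueError(
                f"infeasible spec: a {lengths[0]}-residue tract cannot fit in "
                f"a {seq_len}-residue sequence with flanking gaps"
            )
        lengths.pop()
    free = seq_len - sum(lengths)
    # split the free residues into n+1 gaps, interior gaps >= 1
    n_gaps = len(lengths) + 1
    interior = n_gaps - 2
    cuts = np.sort(rng.integers(0, free - interior + 1, size=n_gaps - 1))
    gap_sizes = np.diff(np.concatenate([[0], cuts, [free - interior]])).tolist()
    for i in range(1, n_gaps - 1):
        gap_sizes[i] += 1
    parts: list[str] = []
    tracts: list[tuple[int, int]] = []
    offset = 0
    for i, tract_len in enumerate(lengths):
        gap = _gap(rng, gap_sizes[i], spec)
        parts.append(gap)
        offset += len(gap)
        tracts.append((offset, tract_len))
        parts.append("P" * tract_len)
        offset += tract_len
    parts.append(_gap(rng, gap_sizes[-1], spec))
    return "".join(parts), tracts


def gen_proteome(spec: ProteomeSpec) -> SyntheticProteome:
    """Generate the two-class proteome; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    rows: list[tuple] = []
    set_width = len(str(spec.n_set))
    bg_width = len(str(spec.n_background))
    for cls, n, p_carrier, prefix, width in (
        ("set", spec.n_set, spec.p_ppt_set, "SET", set_width),
        ("background", spec.n_background, spec.p_ppt_background, "BG", bg_width),
    ):
        for i in range(n):
            pid = f"{prefix}{i + 1:0{width}d}"
            carrier = bool(rng.random() < p_carrier)
            seq, tracts = _one_sequence(rng, carrier, spec)
            records.append((pid, seq))
            if tracts:
                for start, length in tracts:
                    rows.append((pid, cls, len(seq), start, length))
            else:
                rows.append((pid, cls, len(seq), -1, 0))
    truth = pd.DataFrame(
        rows, columns=["protein_id", "class", "seq_length", "start", "length"]
    )
    gene_set = GeneSet(
        name="set",
        members=frozenset(pid for pid, _ in records[: spec.n_set]),
    )
    return SyntheticProteome(
        spec=spec, records=tuple(records), truth=truth, gene_set=gene_set
    )


# ---------------------------------------------------------------------------
# polysome trace


@dataclass(frozen=True)
class TraceSpec:
    """Sum-of-Gaussians absorbance trace on a drifting linear baseline.

    Default layout is a typical 15-50% sucrose gradient read at A254:
    subunit peaks at positions 25/35/45 followed by four polysome peaks,
    with true areas giving a polysome-to-monosome ratio of 2.5 and a
    60S/80S ratio of 0.375. ``noise_sd`` is additive Gaussian noise
    expressed as a fraction of the 80S peak height.
    """

    centres: tuple[float, ...] = (25.0, 35.0, 45.0, 57.0, 68.0, 79.0, 90.0)
    widths: tuple[float, ...] = (1.2, 1.2, 1.4, 1.2, 1.4, 1.6, 1.8)
    areas: tuple[float, ...] = (1.0, 1.5, 4.0, 4.0, 3.0, 2.0, 1.0)
    labels: tuple[str, ...] = (
        "40S", "60S", "80S", "polysome_1", "polysome_2", "polysome_3", "polysome_4",
    )
    baseline_intercept: float = 0.05
    baseline_slope: float = 0.001
    noise_sd: float = 0.02
    span: tuple[float, float] = (0.0, 100.0)
    n_samples: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.centres)
        if not (len(self.widths) == len(self.areas) == len(self.labels) == k):
            raise ValueError("centres, widths, areas and labels must have equal length")
        if not all(c2 > c1 for c1, c2 in zip(self.centres, self.centres[1:])):
            raise ValueError("peak centres must be strictly increasing")
        if any(a <= 0 for a in self.areas) or any(w <= 0 for w in self.widths):
            raise ValueError("areas and widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for (c1, w1), (c2, w2) in zip(
            zip(self.centres, self.widths), zip(self.centres[1:], self.widths[1:])
        ):
            if c2 - c1 < max(w1, w2):
                warnings.warn(
                    f"peak centres {c1} and {c2} are closer than one width; "
                    "peaks may merge",
                    stacklevel=2,
                )

    @property
    def truth(self) -> dict:
        """Ground-truth areas and ratios implied by the spec."""
        areas = dict(zip(self.labels, self.areas))
        poly = sum(a for lbl, a in areas.items() if lbl.startswith("polysome"))
        return {
            "areas": areas,
            "pm_ratio": poly / areas["80S"] if "80S" in areas else float("nan"),
            "ratio_60_80": areas["60S"] / areas["80S"]
            if "60S" in areas and "80S" in areas else float("nan"),
        }


def gen_trace(spec: TraceSpec) -> tuple[Trace, dict]:
    """Generate the trace and return it with the spec's truth record."""
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(spec.span[0], spec.span[1], spec.n_samples)
    y = spec.baseline_intercept + spec.baseline_slope * x
    for centre, width, area in zip(spec.centres, spec.widths, spec.areas):
        y = y + area / (width * math.sqrt(2 * math.pi)) * np.exp(
            -((x - centre) ** 2) / (2 * width**2)
        )
    if spec.noise_sd > 0:
        i80 = spec.labels.index("80S") if "80S" in spec.labels else int(np.argmax(spec.areas))
        height_80s = spec.areas[i80] / (spec.widths[i80] * math.sqrt(2 * math.pi))
        y = y + rng.normal(0.0, spec.noise_sd * height_80s, size=x.size)
    return Trace(positions=x, absorbance=y), spec.truth


# ---------------------------------------------------------------------------
# western blot


@dataclass(frozen=True)
class BlotSpec:
    """Grouped blot lanes under multiplicative lognormal noise.

    ``group_means`` are the true test-antibody expression levels per
    group (control first); the control antibody reports lane loading
    only. ``loading_sd`` and ``measurement_sd`` are standard deviations
    of the underlying normal on the log scale. Defaults model the
    assays emulated here: six replicate lanes per group and 20%
    lane-loading variation.
    """

    group_means: tuple[tuple[str, float], ...] = (("WT", 1.0), ("mutant", 0.4))
    lanes_per_group: int = 6
    loading_sd: float = 0.2
    measurement_sd: float = 0.05
    test_antibody: str = "eIF5A"
    control_antibody: str = "Pab1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lanes_per_group < 2:
            raise ValueError("need at least 2 lanes per group")
        if any(m <= 0 for _, m in self.group_means):
            raise ValueError("group means must be positive")
        if self.loading_sd < 0 or self.measurement_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def gen_blot(spec: BlotSpec) -> tuple[BlotTable, pd.DataFrame]:
    """Generate one blot; returns the table and a lane-level truth frame.

    Per lane: ``Tab = group_mean * loading * eps`` and
    ``Cab = loading * eps'`` with ``loading`` and the two measurement
    errors independent lognormals. With all SDs zero the normalized
    ratios are exactly the group means divided by their blot-wide mean.
    """
    rng = np.random.default_rng(spec.seed)
    lanes: list[str] = []
    groups: list[str] = []
    tab: list[float] = []
    cab: list[float] = []
    for group, mean in spec.group_means:
        for r in range(spec.lanes_per_group):
            loading = float(np.exp(rng.normal(0.0, spec.loading_sd)))
            eps_t = float(np.exp(rng.normal(0.0, spec.measurement_sd)))
            eps_c = float(np.exp(rng.normal(0.0, spec.measurement_sd)))
            lanes.append(f"{group}_{r + 1}")
            groups.append(group)
            tab.append(mean * loading * eps_t)
            cab.append(loading * eps_c)
    table = BlotTable(
        lanes=tuple(lanes),
        signals={spec.test_antibody: tuple(tab), spec.control_antibody: tuple(cab)},
        test_antibody=spec.test_antibody,
        control_antibody=spec.control_antibody,
    )
    truth = pd.DataFrame(
        {
            "lane": lanes,
            "group": groups,
            "true_mean": [dict(spec.group_means)[g] for g in groups],
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class CtSpec:
    """CT pairs for samples with known true relative expression."""

    true_expression: tuple[tuple[str, float], ...] = (
        ("control_1", 1.0), ("control_2", 1.0), ("patient", 0.5),
    )
    reference_ct_mean: float = 20.0
    ct_sd: float = 0.15
    seed: int = 0


def gen_ct_table(spec: CtSpec) -> pd.DataFrame:
    """Columns ``sample, target_ct, reference_ct, true_rel_expr``."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sample, expr in spec.true_expression:
        if expr <= 0:
            raise ValueError(f"true expression for {sample!r} must be positive")
        ref = spec.reference_ct_mean + rng.normal(0.0, spec.ct_sd)
        target = ref - math.log2(expr) + rng.normal(0.0, spec.ct_sd)
        rows.append((sample, target, ref, expr))
    return pd.DataFrame(
        rows, columns=["sample", "target_ct", "reference_ct", "true_rel_expr"]
    )


def with_seed(spec, seed: int):
    """Copy of any generator spec with a new seed."""
    return replace(spec, seed=seed)
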