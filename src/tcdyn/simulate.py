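"""Synthetic time-course expression data with planted temporal structure.

Generates seeded gene × sample log2 expression matrices emulating an RMA-style
microarray time course (six ages × three replicates by default): a static
majority around a common baseline, dynamic genes following planted single-peak
or bimodal temporal templates whose log2 amplitude clears the 2-fold rule,
optional gene sets aligned to templates (to seed coregulated enrichment
tracks), and designated hub genes wired for maximal intramodular connectivity.

Every draw flows from ``SimulationConfig.seed`` through independent
substreams, so the matrix, the gene sets and the ground truth are each
reproducible bit-for-bit regardless of call order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import InvalidDesignError, TimeCourseMatrix
from .pathways import GeneSetCollection

__all__ = [
    "PatternTemplate",
    "HubSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_templates",
    "generate_timecourse",
    "generate_gene_sets",
]

DEFAULT_TIME_POINTS = (0.6, 1, 2.5, 4, 6, 12)  # months; labels only


@dataclass(frozen=True)
class PatternTemplate:
    """A planted temporal expression shape.

    ``profile`` holds one relative log2 offset per time-point; before use it
    is rescaled so its largest absolute offset equals the config amplitude.
    """

    name: str
    profile: tuple
    kind: str = "unimodal"  # unimodal | bimodal
    direction: str = "up"  # up | down

    def scaled(self, amplitude: float) -> np.ndarray:
        prof = np.asarray(self.profile, dtype=float)
        peak = np.abs(prof).max()
        if peak == 0:
            raise ValueError(f"template {self.name!r} has an all-zero profile")
        return prof * (amplitude / peak)


@dataclass(frozen=True)
class HubSpec:
    """Hub wiring inside each template's gene module.

    ``n_hubs`` genes per template are designated hubs.  All template members
    load on a shared per-sample latent factor (hubs with loading ``strength``,
    other members with half that), and non-hub members additionally receive a
    small per-gene temporal jitter (``member_jitter_sd``, log2) so that hubs —
    which track the template exactly — have the highest expected intramodular
    connectivity by construction.
    """

    n_hubs: int = 5
    strength: float = 0.9
    member_jitter_sd: float = 0.3


@dataclass
class SimulationConfig:
    n_static: int = 4400
    n_dynamic: int = 600
    templates: list = field(default_factory=lambda: default_templates())
    time_points: tuple = DEFAULT_TIME_POINTS
    replicates: int = 3
    noise_sd: float = 0.25
    base_mean: float = 6.0
    amplitude: float = 2.0
    n_sets: int = 15
    set_size: int = 25
    aligned_fraction: float = 1.0
    hub_spec: HubSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise InvalidDesignError("replicates must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_static < 0 or self.n_dynamic < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_static + self.n_dynamic <= 0:
            raise ValueError("empty gene universe")
        if self.n_sets < 0 or self.set_size <= 0:
            raise ValueError("gene-set controls must be positive")
        if self.n_dynamic > 0 and not self.templates:
            raise ValueError("dynamic genes requested but no templates given")
        if self.amplitude <= 1.0:
            warnings.warn(
                "amplitude <= 1.0 log2: planted genes may fail the 2-fold rule",
                UserWarning,
                stacklevel=2,
            )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream ``stream`` of the config seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted labels backing every downstream recovery test."""

    labels: dict  # gene -> 'static' | template name
    fold_change: dict  # gene -> planted linear fold change
    hubs: dict = field(default_factory=dict)  # template name -> [gene ids]
    set_membership: dict = field(default_factory=dict)  # set name -> [gene ids]
    set_alignment: dict = field(default_factory=dict)  # set name -> template | None
    warnings: list = field(default_factory=list)

    def genes_of(self, template: str) -> list:
        return [g for g, lab in self.labels.items() if lab == template]

    def dynamic_genes(self) -> list:
        return [g for g, lab in self.labels.items() if lab != "static"]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": self.labels,
                    "fold_change": self.fold_change,
                    "hubs": self.hubs,
                    "set_membership": self.set_membership,
                    "set_alignment": self.set_alignment,
                    "warnings": self.warnings,
                },
                fh,
                indent=1,
            )


def default_templates(n_timepoints: int = 6) -> list:
    """Six mutually dissimilar temporal shapes (single peaks up and down at
    early/middle/late ages plus one bimodal pattern), echoing the kinds of
    nonredundant patterns a six-age time course supports."""
    if n_timepoints != 6:
        raise ValueError("default templates are defined for 6 time-points")
    return [
        PatternTemplate("up_t1", (1, 0, 0, 0, 0, 0), "unimodal", "up"),
        PatternTemplate("up_t3", (0, 0, 1, 0, 0, 0), "unimodal", "up"),
        PatternTemplate("up_t6", (0, 0, 0, 0, 0, 1), "unimodal", "up"),
        PatternTemplate("down_t1", (-1, 0, 0, 0, 0, 0), "unimodal", "down"),
        PatternTemplate("down_t4", (0, 0, 0, -1, 0, 0), "unimodal", "down"),
        PatternTemplate("bimodal_t2_t5", (0, 1, 0, 0, 1, 0), "bimodal", "up"),
    ]


def _split_counts(total: int, parts: int) -> list:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def generate_timecourse(config: SimulationConfig):
    """Draw a seeded (TimeCourseMatrix, GroundTruth) pair.

    Dynamic genes get expected per-time-point log2 means of
    ``base_mean + scaled template profile``; replicate values add i.i.d.
    Gaussian(0, noise_sd) on the log2 scale (log-normal on linear scale).
    With ``hub_spec`` set, template members share a latent per-sample factor
    and non-hub members receive per-gene temporal jitter (see
    :class:`HubSpec`).
    """
    rng = config.rng(0)
    n_t, n_rep = len(config.time_points), config.replicates
    n_samples = n_t * n_rep

    sample_ids, tp_col, rep_col = [], [], []
    for ti, t in enumerate(config.time_points):
        for r in range(1, n_rep + 1):
            sample_ids.append(f"T{ti + 1}_R{r}")
            tp_col.append(t)
            rep_col.append(r)
    design = pd.DataFrame({"time_point": tp_col, "replicate": rep_col}, index=sample_ids)
    tp_of_sample = np.repeat(np.arange(n_t), n_rep)

    n_genes = config.n_static + config.n_dynamic
    width = len(str(n_genes))
    labels: dict = {}
    fold: dict = {}
    hubs: dict = {}
    rows = np.empty((n_genes, n_samples))
    gene_ids = []
    truth_warnings = []
    if config.amplitude <= 1.0:
        truth_warnings.append("amplitude <= 1.0 log2; planted genes may fail the 2-fold rule")

    gi = 0
    if config.n_dynamic:
        counts = _split_counts(config.n_dynamic, len(config.templates))
        for tmpl, cnt in zip(config.templates, counts):
            prof = tmpl.scaled(config.amplitude)
            if len(prof) != n_t:
                raise ValueError(
                    f"template {tmpl.name!r} has {len(prof)} offsets for {n_t} time-points"
                )
            means = config.base_mean + prof
            planted_fc = float(2.0 ** (prof.max() - prof.min()))
            member_ids = []
            for _ in range(cnt):
                gid = f"G{gi:0{width}d}"
                gene_ids.append(gid)
                member_ids.append(gid)
                labels[gid] = tmpl.name
                fold[gid] = planted_fc
                gi += 1
            base = np.tile(means[tp_of_sample], (cnt, 1))
            if config.hub_spec is not None and cnt > 0:
                spec = config.hub_spec
                n_h = min(spec.n_hubs, cnt)
                hub_idx = rng.choice(cnt, size=n_h, replace=False)
                hub_mask = np.zeros(cnt, dtype=bool)
                hub_mask[hub_idx] = True
                hubs[tmpl.name] = [member_ids[j] for j in np.flatnonzero(hub_mask)]
                factor = rng.standard_normal(n_samples)
                lam = np.where(hub_mask, spec.strength, spec.strength / 2.0)
                noise = rng.standard_normal((cnt, n_samples))
                shared = lam[:, None] * factor[None, :]
                idio = np.sqrt(1.0 - lam**2)[:, None] * noise
                base += config.noise_sd * (shared + idio)
                jitter = rng.normal(0.0, spec.member_jitter_sd, size=(cnt, n_t))
                jitter[hub_mask] = 0.0
                base += jitter[:, tp_of_sample]
            else:
                base += rng.normal(0.0, config.noise_sd, size=(cnt, n_samples))
            rows[gi - cnt : gi] = base

    for _ in range(config.n_static):
        gid = f"G{gi:0{width}d}"
        gene_ids.append(gid)
        labels[gid] = "static"
        fold[gid] = 1.0
        gi += 1
    if config.n_static:
        rows[gi - config.n_static : gi] = config.base_mean + rng.normal(
            0.0, config.noise_sd, size=(config.n_static, n_samples)
        )

    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    matrix = TimeCourseMatrix(values=values, design=design)
    truth = GroundTruth(labels=labels, fold_change=fold, hubs=hubs, warnings=truth_warnings)
    return matrix, truth


def generate_gene_sets(
    truth: GroundTruth, config: SimulationConfig, alignment: list | None = None
) -> GeneSetCollection:
    """Draw ``config.n_sets`` gene sets of ``config.set_size`` members.

    ``alignment`` lists, per set, the template name it is aligned to (or None
    for a uniform random set); by default the first sets are aligned
    round-robin over the templates with planted genes.  An aligned set takes
    ``round(aligned_fraction * set_size)`` members from that template's genes
    and fills the rest uniformly at random from the remaining universe.
    """
    rng = config.rng(1)
    universe = np.array(list(truth.labels))
    if config.set_size > len(universe):
        raise ValueError(
            f"set_size {config.set_size} exceeds universe of {len(universe)} genes"
        )
    template_names = [t for t in (tm.name for tm in config.templates) if truth.genes_of(t)]
    if alignment is None:
        alignment = [
            template_names[i % len(template_names)] if template_names and config.aligned_fraction > 0 else None
            for i in range(min(config.n_sets, max(len(template_names), 0)))
        ]
    alignment = list(alignment) + [None] * (config.n_sets - len(alignment))

    sets: dict = {}
    for i, tmpl_name in enumerate(alignment[: config.n_sets]):
        name = f"SET{i + 1:02d}" + (f"_{tmpl_name}" if tmpl_name else "_random")
        if tmpl_name is not None:
            pool = np.array(truth.genes_of(tmpl_name))
            n_aligned = min(int(round(config.aligned_fraction * config.set_size)), len(pool))
            chosen = list(rng.choice(pool, size=n_aligned, replace=False))
            rest_pool = np.setdiff1d(universe, np.array(chosen, dtype=universe.dtype))
            n_rest = config.set_size - n_aligned
            chosen += list(rng.choice(rest_pool, size=n_rest, replace=False))
        else:
            chosen = list(rng.choice(universe, size=config.set_size, replace=False))
        sets[name] = [str(g) for g in chosen]
        truth.set_membership[name] = sets[name]
        truth.set_alignment[name] = tmpl_name
    return GeneSetCollection(sets=sets, source="synthetic")
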