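"""Seeded synthetic four-stage count datasets with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial counts (variance μ + αμ²) over four ordered
flower-development stages with replicate libraries, stage-specific planted
fold changes, GO terms over-assigned to the planted differential genes, and
regulator genes whose profiles copy (positive control) or mirror (negative
control) a structural gene's profile, mimicking MYB/bHLH/WD40 regulation of
the flavonoid structural families.

Every draw is derived from a single master seed through named child
streams, so enlarging one part of the catalog does not perturb unrelated
draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SampleSheet, DEFAULT_STAGES, write_counts, \
    write_sample_sheet, write_table

#: structural-family member counts (flavonoid biosynthetic enzymes)
STRUCTURAL_FAMILIES: dict[str, int] = {
    "CHS": 14, "CHI": 4, "FNS": 2, "F3H": 10, "F3'H": 7,
    "F3'5'H": 18, "FLS": 17, "DFR": 8, "ANS": 4, "3GT": 13,
}

#: regulator-family member counts (MBW-complex transcription factors)
REGULATOR_FAMILIES: dict[str, int] = {"MYB": 25, "bHLH": 20, "WD40": 37}

REGULATOR_FAMILY_NAMES = tuple(REGULATOR_FAMILIES)


class MotifSpec(NamedTuple):
    """One planted regulatory triple: a structural gene, its positively
    correlated regulator and its negatively correlated regulator."""

    structural: str
    positive: str
    negative: str


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_genes: int = 2000
    stages: tuple[str, ...] = DEFAULT_STAGES
    reps_per_stage: int = 2
    #: log10 range of baseline mean expression
    baseline_mean_log_range: tuple[float, float] = (0.5, 3.0)
    #: NB overdispersion α in var = μ + αμ²
    dispersion: float = 0.1
    n_planted_deu_per_phase: int = 30
    planted_log2fc: float = 3.0
    #: planted differential genes get baseline means at or above this
    planted_min_baseline: float = 50.0
    family_spec: dict[str, int] = field(
        default_factory=lambda: {**STRUCTURAL_FAMILIES, **REGULATOR_FAMILIES}
    )
    go_terms: int = 200
    #: mean GO terms per gene (Poisson)
    go_lambda: float = 3.0
    planted_enriched_terms: int = 5
    #: probability a planted enriched term is over-assigned to a planted DEU
    enrich_assign_rate: float = 0.6
    #: planted regulatory triples; None selects a default set from the catalog
    motif_spec: list[MotifSpec] | None = None
    #: multiplicative noise sd on planted regulator counts (σ = noise·μ)
    motif_noise: float = 0.1
    length_range: tuple[int, int] = (200, 3000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.reps_per_stage < 1:
            raise ValueError("reps_per_stage must be >= 1")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if any(v < 0 for v in self.family_spec.values()):
            raise ValueError("family member counts must be >= 0")
        n_family = sum(self.family_spec.values())
        if n_family > self.n_genes:
            raise ValueError(
                f"family members ({n_family}) exceed n_genes ({self.n_genes}); "
                "increase n_genes or shrink family_spec"
            )
        n_phases = len(self.stages) - 1
        planted = self.n_planted_deu_per_phase * n_phases
        if planted > self.n_genes - n_family:
            raise ValueError(
                f"{planted} planted DEUs do not fit among the "
                f"{self.n_genes - n_family} unassigned genes"
            )
        if self.planted_enriched_terms > self.go_terms:
            raise ValueError("planted_enriched_terms exceeds go_terms")

    def to_json(self) -> str:
        payload = asdict(self)
        if payload["motif_spec"] is not None:
            payload["motif_spec"] = [list(m) for m in payload["motif_spec"]]
        return json.dumps(payload, indent=2)


@dataclass
class GeneCatalog:
    """Gene ids, lengths, family labels and GO annotations, plus the
    pre-selected planted gene/term identities."""

    table: pd.DataFrame  # gene_id (index), length, family
    gene2go: pd.DataFrame  # gene_id, go_id
    planted_deu: dict[str, list[str]]  # phase label -> gene ids
    enriched_terms: list[str]

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def family_members(self, family: str) -> list[str]:
        return list(self.table.index[self.table["family"] == family])

    @property
    def regulators(self) -> list[str]:
        mask = self.table["family"].isin(REGULATOR_FAMILY_NAMES)
        return list(self.table.index[mask])

    @property
    def structurals(self) -> list[str]:
        mask = self.table["family"].isin(STRUCTURAL_FAMILIES)
        return list(self.table.index[mask])


@dataclass
class SimTruth:
    """Ground truth of every planting."""

    deu: pd.DataFrame  # phase, gene_id, log2fc (signed)
    enriched_terms: list[str]
    motifs: pd.DataFrame  # structural, regulator, sign (+1/-1)

    def deu_genes(self, phase: str) -> list[str]:
        return list(self.deu.loc[self.deu["phase"] == phase, "gene_id"])

    @property
    def all_deu_genes(self) -> list[str]:
        return list(dict.fromkeys(self.deu["gene_id"]))


def phase_labels(stages: Sequence[str]) -> list[str]:
    """Labels of the sequential stage comparisons.

    The default four stages map to the named growth phases early
    (BD→BB), middle (BB→EB) and mature (EB→FB).
    """
    if tuple(stages) == DEFAULT_STAGES:
        return ["early", "middle", "mature"]
    return [f"{a}-{b}" for a, b in zip(stages[:-1], stages[1:])]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(7)
    names = ("lengths", "go", "planting", "baseline", "counts", "profiles", "motif")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def generate_catalog(config: SimConfig) -> GeneCatalog:
    """Build the gene catalog: ids, lengths, family labels, GO annotations.

    Family labels are assigned to the first Σ(member counts) genes in the
    order of ``family_spec``.  Each gene draws Poisson(go_lambda) distinct GO
    terms uniformly; the planted enriched terms are then over-assigned to
    the pre-selected planted differential genes at ``enrich_assign_rate``.
    """
    config.validate()
    rngs = _streams(config.seed)

    width = max(5, len(str(config.n_genes)))
    gene_ids = [f"u{i:0{width}d}" for i in range(config.n_genes)]
    lengths = rngs["lengths"].integers(
        config.length_range[0], config.length_range[1] + 1, size=config.n_genes
    )

    family = np.array([""] * config.n_genes, dtype=object)
    pos = 0
    for name, count in config.family_spec.items():
        family[pos : pos + count] = name
        pos += count

    table = pd.DataFrame(
        {"length": lengths, "family": family}, index=pd.Index(gene_ids, name="gene_id")
    )

    # pre-select planted differential genes among family-free genes
    phases = phase_labels(config.stages)
    eligible = list(table.index[pos:])
    rng_plant = rngs["planting"]
    chosen = rng_plant.choice(
        len(eligible),
        size=config.n_planted_deu_per_phase * len(phases),
        replace=False,
    )
    planted_deu: dict[str, list[str]] = {}
    for i, phase in enumerate(phases):
        block = chosen[
            i * config.n_planted_deu_per_phase : (i + 1) * config.n_planted_deu_per_phase
        ]
        planted_deu[phase] = [eligible[j] for j in sorted(block)]

    # baseline GO annotation
    term_ids = [f"GO:{i:07d}" for i in range(config.go_terms)]
    rng_go = rngs["go"]
    n_terms = rng_go.poisson(config.go_lambda, size=config.n_genes)
    n_terms = np.minimum(n_terms, config.go_terms)
    records: list[tuple[str, str]] = []
    for gene, k in zip(gene_ids, n_terms):
        if k == 0:
            continue
        for t in rng_go.choice(config.go_terms, size=k, replace=False):
            records.append((gene, term_ids[t]))

    enriched = [term_ids[t] for t in rng_plant.choice(
        config.go_terms, size=config.planted_enriched_terms, replace=False
    )]
    assigned = {(g, t) for g, t in records}
    all_planted = [g for phase in phases for g in planted_deu[phase]]
    for term in enriched:
        hits = rng_plant.random(len(all_planted)) < config.enrich_assign_rate
        for gene, hit in zip(all_planted, hits):
            if hit and (gene, term) not in assigned:
                records.append((gene, term))
                assigned.add((gene, term))

    gene2go = pd.DataFrame(records, columns=["gene_id", "go_id"])
    gene2go = gene2go.sort_values(["gene_id", "go_id"], kind="stable").reset_index(drop=True)
    return GeneCatalog(
        table=table, gene2go=gene2go, planted_deu=planted_deu, enriched_terms=enriched
    )


def default_motif_spec(catalog: GeneCatalog, n: int = 6) -> list[MotifSpec]:
    """A default planted motif set: one structural gene from each of ``n``
    families, a positive regulator drawn from MYB/bHLH/WD40 in turn and a
    negative (repressor-like) MYB regulator."""
    structural_pool = [
        fam for fam in ("CHS", "CHI", "F3H", "FLS", "DFR", "3GT", "ANS", "F3'H")
        if catalog.family_members(fam)
    ][:n]
    myb = catalog.family_members("MYB")
    bhlh = catalog.family_members("bHLH")
    wd40 = catalog.family_members("WD40")
    positives = [myb[0], myb[1], bhlh[0], bhlh[1], wd40[0], wd40[1]]
    negatives = myb[10:16]
    spec = []
    for i, fam in enumerate(structural_pool):
        spec.append(
            MotifSpec(
                structural=catalog.family_members(fam)[0],
                positive=positives[i % len(positives)],
                negative=negatives[i % len(negatives)],
            )
        )
    return spec


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Sample NB(mean μ, var μ + αμ²); α = 0 is the Poisson limit."""
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(
    catalog: GeneCatalog, config: SimConfig
) -> tuple[CountMatrix, SimTruth]:
    """Sample the count matrix and assemble the ground-truth tables.

    Planted differential genes receive a 2^±planted_log2fc multiplicative
    step on the later stage of their phase **and all subsequent stages**, so
    the change is confined to that single sequential comparison.  Planted
    regulator genes are overwritten sample-wise from their structural gene's
    realized counts: positives copy the counts exactly, negatives mirror
    them on the log2(x+1) scale (y+1 = (max+1)(min+1)/(x+1), rounded), then
    multiplicative noise of sd ``motif_noise``·μ is applied.
    """
    config.validate()
    rngs = _streams(config.seed)
    n_stages = len(config.stages)
    phases = phase_labels(config.stages)

    lo, hi = config.baseline_mean_log_range
    baseline = 10.0 ** rngs["baseline"].uniform(lo, hi, size=config.n_genes)
    gene_pos = {g: i for i, g in enumerate(catalog.genes)}

    # planted genes get detectable baselines and a signed fold-change step
    mu = np.tile(baseline[:, None], (1, n_stages))
    deu_rows: list[dict[str, object]] = []
    floor = max(config.planted_min_baseline, 10.0**lo)
    for phase_idx, phase in enumerate(phases):
        for j, gene in enumerate(catalog.planted_deu[phase]):
            i = gene_pos[gene]
            if baseline[i] < floor:
                mu[i, :] = 10.0 ** rngs["baseline"].uniform(np.log10(floor), hi)
            sign = 1 if j % 2 == 0 else -1
            mu[i, phase_idx + 1 :] *= 2.0 ** (sign * config.planted_log2fc)
            deu_rows.append(
                {"phase": phase, "gene_id": gene,
                 "log2fc": sign * config.planted_log2fc}
            )

    motif_spec = config.motif_spec
    if motif_spec is None:
        motif_spec = default_motif_spec(catalog)

    # planted structural genes get a distinctive random stage profile so the
    # regulator correlation carries real stage signal
    for m in motif_spec:
        i = gene_pos[m.structural]
        mu[i, :] *= 2.0 ** rngs["profiles"].normal(0.0, 1.0, size=n_stages)

    samples: dict[str, tuple[str, int]] = {}
    columns: list[str] = []
    rng_counts = rngs["counts"]
    count_cols: dict[str, np.ndarray] = {}
    for s, stage in enumerate(config.stages):
        for rep in range(1, config.reps_per_stage + 1):
            name = f"{stage}_{rep}"
            samples[name] = (stage, rep)
            columns.append(name)
            count_cols[name] = _nb_draw(rng_counts, mu[:, s], config.dispersion)

    counts = pd.DataFrame(count_cols, index=catalog.genes, columns=columns)

    # overwrite planted regulators from realized structural counts
    rng_motif = rngs["motif"]
    motif_rows: list[dict[str, object]] = []
    for m in motif_spec:
        x = counts.loc[m.structural].to_numpy(dtype=float)
        pos_vals = x.copy()
        mirrored = (x.max() + 1.0) * (x.min() + 1.0) / (x + 1.0) - 1.0
        for reg, base, sign in ((m.positive, pos_vals, 1), (m.negative, mirrored, -1)):
            vals = base
            if config.motif_noise > 0:
                vals = vals * (1.0 + rng_motif.normal(0.0, config.motif_noise, vals.shape))
            counts.loc[reg] = np.maximum(0, np.round(vals)).astype(np.int64)
            motif_rows.append(
                {"structural": m.structural, "regulator": reg, "sign": sign}
            )

    sheet = SampleSheet(samples=samples, stages=config.stages)
    cm = CountMatrix(counts=counts, lengths=catalog.table["length"].copy(), sheet=sheet)
    truth = SimTruth(
        deu=pd.DataFrame(deu_rows, columns=["phase", "gene_id", "log2fc"]),
        enriched_terms=list(catalog.enriched_terms),
        motifs=pd.DataFrame(motif_rows, columns=["structural", "regulator", "sign"]),
    )
    return cm, truth


def write_dataset(
    out_dir: str | Path,
    config: SimConfig,
    catalog: GeneCatalog,
    cm: CountMatrix,
    truth: SimTruth,
) -> dict[str, str]:
    """Write the dataset as diffable TSV/JSON files; returns a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    write_counts(cm, out / "counts.tsv")
    manifest["counts"] = "counts.tsv"
    write_sample_sheet(cm.sheet, out / "samples.tsv")
    manifest["samples"] = "samples.tsv"
    write_table(catalog.gene2go, out / "gene2go.tsv")
    manifest["gene2go"] = "gene2go.tsv"
    fam = catalog.table.loc[catalog.table["family"] != "", ["family"]].reset_index()
    write_table(fam, out / "families.tsv")
    manifest["families"] = "families.tsv"
    write_table(truth.deu, out / "truth_deu.tsv")
    manifest["truth_deu"] = "truth_deu.tsv"
    write_table(truth.motifs, out / "truth_motifs.tsv")
    manifest["truth_motifs"] = "truth_motifs.tsv"
    write_table(
        pd.DataFrame({"go_id": truth.enriched_terms}), out / "truth_enriched_terms.tsv"
    )
    manifest["truth_enriched_terms"] = "truth_enriched_terms.tsv"
    (out / "config.json").write_text(config.to_json())
    manifest["config"] = "config.json"
    return manifest
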