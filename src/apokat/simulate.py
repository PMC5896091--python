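"""Synthetic cell-line panels with full ground truth.

Every analysis stage in the package can be exercised without external
downloads: this module generates

* a small random genome (FASTA, with per-chromosome base composition),
* per-cell-line SNV catalogs (VCF) mixing uniform background substitutions,
  planted strand-coordinated motif clusters, and a configurable fraction of
  common population variants (panel allele frequency > 1%),
* phenotype tables — log2 expression per gene (unimodal Gaussian or a
  two-component mixture, emulating the bimodal pattern seen for APOBEC3B),
  drug log10(IC50) columns with planted monotone associations to expression
  at a chosen Spearman rho, and a cell line -> cancer-category map,

together with truth tables recording exactly what was planted where.

Planted clusters are placed on sites whose *existing* reference context
matches the requested motif — the genome is searched, never edited — so
motif classification runs against realistic context scarcity.  Cluster
sites are chosen with flank/alt combinations specific to the requested
motif class (a T(C>K)W cluster is planted with 3' T so it does not shadow
T(C>D)R, and a T(C>D)D cluster with 3' T and alt A so it shadows neither
narrower motif); since every narrow-motif event is also a T(C>D)D event,
the truth table enumerates those implied T(C>D)D clusters explicitly.

Randomness: one documented child stream per output (0 = genome,
1 = catalogs, 2 = phenotypes), derived from the master seed with
``numpy.random.SeedSequence(seed, spawn_key=(stream,))``, so any table can
be regenerated independently of the others.  All outputs are bit-identical
given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import COMPLEMENT, SNVRecord
from .correlation import PAN_CANCER
from .motifs import MOTIF_CLASSES
from .phenotype import DrugResponseTable, ExpressionTable

BASES = ("A", "C", "G", "T")

GENOME_STREAM, CATALOG_STREAM, PHENOTYPE_STREAM = 0, 1, 2

#: (context5 required base, alt choices, context3 required base) per
#: (motif, strand) used when *planting* clusters.  Restricting the 3' flank
#: keeps each planted cluster specific: its events match the requested
#: motif (plus the umbrella TCDD motif) and no other.
_PLANT_SITE: dict[tuple[str, str], tuple[str, tuple[str, ...], str]] = {
    ("TCKW", "+"): ("T", ("G", "T"), "T"),
    ("TCDR", "+"): ("T", ("A", "G", "T"), "G"),
    ("TCDD", "+"): ("T", ("A",), "T"),
}
for (_m, _s), (_c5, _alts, _c3) in list(_PLANT_SITE.items()):
    # minus strand: the reference-strand triplet is the reverse complement
    _PLANT_SITE[(_m, "-")] = (
        COMPLEMENT[_c3],
        tuple(COMPLEMENT[a] for a in _alts),
        COMPLEMENT[_c5],
    )


@dataclass(frozen=True)
class PlantedClusterSpec:
    """Request to plant ``count`` clusters of ``n_events`` same-motif
    same-strand events within ``span_bp`` per cell line."""

    motif: str
    strand: str
    n_events: int
    span_bp: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.motif not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif {self.motif!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.n_events < 2 or self.span_bp < self.n_events or self.count < 0:
            raise ValueError("invalid planted-cluster parameters")


@dataclass(frozen=True)
class GeneModel:
    """Expression model for one gene: Gaussian or two-component mixture.

    For ``kind="normal"``, ``means[0]``/``sds[0]`` are used.  For
    ``kind="mixture"``, ``weight_low`` is the probability of the first
    (low) component.
    """

    kind: str  # "normal" | "mixture"
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weight_low: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "mixture"):
            raise ValueError(f"unknown gene model kind {self.kind!r}")
        if self.kind == "mixture":
            if len(self.means) != 2 or len(self.sds) != 2:
                raise ValueError("mixture model needs two means and two sds")
            if not (0.0 < self.weight_low < 1.0):
                raise ValueError("mixture weight must lie in (0,1)")
        if any(s <= 0 for s in self.sds):
            raise ValueError("sds must be positive")


@dataclass(frozen=True)
class AssocSpec:
    """Planted monotone association: variable -> drug at target Spearman rho
    within one stratum (or pan-cancer)."""

    variable: str
    drug: str
    rho: float
    stratum: str = PAN_CANCER

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError(f"target Spearman rho must lie in [-1,1], got {self.rho}")


# Default expression models follow the pan-cancer candidate-gene picture:
# APOBEC3B bimodal (deletion carriers vs expressors), the rest unimodal with
# means/SDs in the ranges reported for large cell-line panels.
DEFAULT_EXPRESSION_MODELS: dict[str, GeneModel] = {
    "APOBEC3B": GeneModel("mixture", (4.0, 10.0), (0.8, 1.0), weight_low=0.35),
    "APOBEC3A": GeneModel("normal", (3.9,), (0.6,)),
    "UNG": GeneModel("normal", (9.4,), (0.8,)),
    "REV1": GeneModel("normal", (7.0,), (0.4,)),
    "FHIT": GeneModel("normal", (5.7,), (1.2,)),
}


@dataclass
class SimulationConfig:
    """Everything the generator needs, with study-scale defaults.

    Defaults are desk-scale stand-ins for a whole-exome cell-line panel:
    a 1.5-Mb three-chromosome genome; a background substitution density of
    1.5e-3 SNVs/bp (the post-filter exome SNV density of heavily mutated
    cancer cell lines); 10% of background variants flagged as common
    population variants; one planted narrow-motif and one planted
    broad-motif cluster per cell line; three cancer categories; thirty
    drug-response columns with a handful of planted associations.
    """

    seed: int = 0
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 600_000, "chr2": 500_000, "chr3": 400_000}
    )
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    categories: dict[str, int] = field(
        default_factory=lambda: {"NSCLC": 8, "BREAST": 6, "BLADDER": 6}
    )
    background_rate: float = 1.5e-3  # SNVs per bp per cell line
    af_common_fraction: float = 0.10  # background variants with pop AF > 1%
    planted_clusters: list[PlantedClusterSpec] = field(
        default_factory=lambda: [
            PlantedClusterSpec("TCKW", "+", n_events=6, span_bp=800, count=1),
            PlantedClusterSpec("TCDR", "-", n_events=7, span_bp=5000, count=1),
        ]
    )
    isolation_bp: int = 10_001  # min gap between a planted cluster and anything else
    expression_models: dict[str, GeneModel] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_MODELS)
    )
    n_drugs: int = 30
    planted_assoc: list[AssocSpec] = field(
        default_factory=lambda: [
            AssocSpec("APOBEC3B", "drug01", rho=0.7),
            AssocSpec("REV1", "drug02", rho=-0.6),
            AssocSpec("APOBEC3A", "drug03", rho=0.5, stratum="NSCLC"),
        ]
    )

    @property
    def n_cell_lines(self) -> int:
        return sum(self.categories.values())

    @property
    def cell_line_ids(self) -> list[str]:
        return [f"CL{i:04d}" for i in range(self.n_cell_lines)]

    def category_map(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        ids = iter(self.cell_line_ids)
        for label, count in self.categories.items():
            for _ in range(count):
                mapping[next(ids)] = label
        return mapping

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )

    # -- plain-dict (YAML-friendly) round trip -------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "chromosomes": dict(self.chromosomes),
            "base_composition": list(self.base_composition),
            "categories": dict(self.categories),
            "background_rate": self.background_rate,
            "af_common_fraction": self.af_common_fraction,
            "planted_clusters": [
                {
                    "motif": p.motif,
                    "strand": p.strand,
                    "n_events": p.n_events,
                    "span_bp": p.span_bp,
                    "count": p.count,
                }
                for p in self.planted_clusters
            ],
            "isolation_bp": self.isolation_bp,
            "expression_models": {
                g: {
                    "kind": m.kind,
                    "means": list(m.means),
                    "sds": list(m.sds),
                    "weight_low": m.weight_low,
                }
                for g, m in self.expression_models.items()
            },
            "n_drugs": self.n_drugs,
            "planted_assoc": [
                {
                    "variable": a.variable,
                    "drug": a.drug,
                    "rho": a.rho,
                    "stratum": a.stratum,
                }
                for a in self.planted_assoc
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        cfg = cls()
        kwargs: dict = {}
        for key in (
            "seed",
            "background_rate",
            "af_common_fraction",
            "isolation_bp",
            "n_drugs",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "chromosomes" in d:
            kwargs["chromosomes"] = dict(d["chromosomes"])
        if "base_composition" in d:
            kwargs["base_composition"] = tuple(d["base_composition"])
        if "categories" in d:
            kwargs["categories"] = dict(d["categories"])
        if "planted_clusters" in d:
            kwargs["planted_clusters"] = [
                PlantedClusterSpec(**p) for p in d["planted_clusters"]
            ]
        if "expression_models" in d:
            kwargs["expression_models"] = {
                g: GeneModel(
                    kind=m["kind"],
                    means=tuple(m["means"]),
                    sds=tuple(m["sds"]),
                    weight_low=m.get("weight_low", 0.5),
                )
                for g, m in d["expression_models"].items()
            }
        if "planted_assoc" in d:
            kwargs["planted_assoc"] = [AssocSpec(**a) for a in d["planted_assoc"]]
        return cls(**{**{}, **kwargs}) if kwargs else cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class PlantedCluster:
    """Ground truth for one planted cluster (event-bounded extent)."""

    cell_line_id: str
    chrom: str
    strand: str
    motif: str
    positions: tuple[int, ...]

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]

    @property
    def n_events(self) -> int:
        return len(self.positions)


@dataclass
class CatalogTruth:
    """What the catalog generator planted.

    ``origins`` maps (cell_line, chrom, pos) to "background", "planted" or
    "common-AF".
    """

    planted: list[PlantedCluster]
    origins: dict[tuple[str, str, int], str]

    def expected_clusters(
        self, k: int, w: int
    ) -> set[tuple[str, str, str, str, int, int, int]]:
        """Detected-cluster truth set under an isolation-respecting (k, w).

        Keys: (cell_line, chrom, strand, motif, start, end, n_events).
        Every planted cluster whose event count reaches k and whose span
        fits in w appears once under its own motif and — because both
        narrow motifs are strict subsets of T(C>D)D — once more under TCDD.
        """
        expected = set()
        for pc in self.planted:
            if pc.n_events < k or pc.end - pc.start > w - 1:
                continue
            for motif in {pc.motif, "TCDD"}:
                expected.add(
                    (
                        pc.cell_line_id,
                        pc.chrom,
                        pc.strand,
                        motif,
                        pc.start,
                        pc.end,
                        pc.n_events,
                    )
                )
        return expected


@dataclass
class PhenotypeTruth:
    """Planted association parameters and the latent drug generation scale."""

    associations: list[AssocSpec]


# --------------------------------------------------------------------------
# genome
# --------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig, fasta_path: str | Path | None = None
) -> dict[str, str]:
    """Draw an i.i.d. random genome with the configured base composition.

    Returns chrom -> sequence; when ``fasta_path`` is given the genome is
    also written as FASTA and faidx-indexed.  Reproducible bit-exactly from
    (config, seed).
    """
    probs = np.asarray(config.base_composition, dtype=float)
    if not math.isclose(float(probs.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("base_composition must sum to 1")
    rng = config.rng(GENOME_STREAM)
    genome: dict[str, str] = {}
    base_arr = np.array(list("ACGT"))
    for chrom, length in config.chromosomes.items():
        if length < 1:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        idx = rng.choice(4, size=length, p=probs)
        genome[chrom] = "".join(base_arr[idx])
    if fasta_path is not None:
        write_genome_fasta(genome, fasta_path)
    return genome


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    import pysam

    path = Path(path)
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pysam.faidx(str(path))


# --------------------------------------------------------------------------
# catalogs
# --------------------------------------------------------------------------

def _plant_site_positions(seq: str, motif: str, strand: str) -> np.ndarray:
    """1-based positions whose reference context supports planting the motif."""
    c5, _alts, c3 = _PLANT_SITE[(motif, strand)]
    center = "C" if strand == "+" else "G"
    arr = np.frombuffer(seq.encode(), dtype="S1")
    hits = (
        (arr[1:-1] == center.encode())
        & (arr[:-2] == c5.encode())
        & (arr[2:] == c3.encode())
    )
    return np.nonzero(hits)[0] + 2  # index i of arr[1:-1] is genome pos i+2


def _choose_cluster_sites(
    candidates: np.ndarray,
    n_events: int,
    span_bp: int,
    blocked: list[tuple[int, int]],
    isolation_bp: int,
    rng: np.random.Generator,
) -> tuple[int, ...] | None:
    """Pick n_events candidate positions spanning <= span_bp, away from
    blocked intervals.  Returns None when no window fits."""
    feasible: list[int] = []
    for i in range(len(candidates) - n_events + 1):
        lo = int(candidates[i])
        hi = int(candidates[i + n_events - 1])
        if hi - lo > span_bp - 1:
            continue
        if any(
            lo - isolation_bp <= b_end and hi + isolation_bp >= b_start
            for b_start, b_end in blocked
        ):
            continue
        feasible.append(i)
    if not feasible:
        return None
    i = int(rng.choice(len(feasible)))
    start = feasible[i]
    return tuple(int(p) for p in candidates[start : start + n_events])


def simulate_catalog(
    config: SimulationConfig, genome: Mapping[str, str]
) -> tuple[dict[str, list[SNVRecord]], CatalogTruth]:
    """Generate per-cell-line SNV catalogs with planted clusters.

    Background SNVs are uniform over the genome with a random alternate
    base, kept at least ``isolation_bp`` away from any planted cluster so
    planted ground truth stays exact.  A configured fraction of background
    variants is flagged as common (pop AF > 1%); planted variants carry no
    panel frequency.  Records are sorted by (chrom, pos).
    """
    rng = config.rng(CATALOG_STREAM)
    chroms = list(config.chromosomes)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    total_len = float(lengths.sum())

    catalogs: dict[str, list[SNVRecord]] = {}
    planted_truth: list[PlantedCluster] = []
    origins: dict[tuple[str, str, int], str] = {}

    for cell in config.cell_line_ids:
        records: list[SNVRecord] = []
        blocked_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        occupied: set[tuple[str, int]] = set()

        # --- planted clusters
        for spec in config.planted_clusters:
            for _copy in range(spec.count):
                placed = False
                order = rng.permutation(len(chroms))
                for ci in order:
                    chrom = chroms[int(ci)]
                    candidates = _plant_site_positions(
                        genome[chrom], spec.motif, spec.strand
                    )
                    sites = _choose_cluster_sites(
                        candidates,
                        spec.n_events,
                        spec.span_bp,
                        blocked_by_chrom[chrom],
                        config.isolation_bp,
                        rng,
                    )
                    if sites is None:
                        continue
                    _c5, alts, _c3 = _PLANT_SITE[(spec.motif, spec.strand)]
                    for pos in sites:
                        seq = genome[chrom]
                        alt = alts[int(rng.integers(len(alts)))]
                        records.append(
                            SNVRecord(
                                cell_line_id=cell,
                                chrom=chrom,
                                pos=pos,
                                ref=seq[pos - 1],
                                alt=alt,
                                context5=seq[pos - 2],
                                context3=seq[pos],
                                pop_af=None,
                            )
                        )
                        occupied.add((chrom, pos))
                        origins[(cell, chrom, pos)] = "planted"
                    blocked_by_chrom[chrom].append((sites[0], sites[-1]))
                    planted_truth.append(
                        PlantedCluster(
                            cell_line_id=cell,
                            chrom=chrom,
                            strand=spec.strand,
                            motif=spec.motif,
                            positions=sites,
                        )
                    )
                    placed = True
                    break
                if not placed:
                    raise RuntimeError(
                        f"no matching context window for {spec.motif}/{spec.strand} "
                        f"(n={spec.n_events}, span={spec.span_bp}); "
                        "use a longer genome"
                    )

        # --- background
        n_background = int(rng.poisson(config.background_rate * total_len))
        placed_bg = 0
        while placed_bg < n_background:
            ci = int(rng.choice(len(chroms), p=lengths / total_len))
            chrom = chroms[ci]
            seq = genome[chrom]
            pos = int(rng.integers(2, len(seq)))  # keep both flanks inside
            if (chrom, pos) in occupied:
                continue
            if any(
                b_start - config.isolation_bp <= pos <= b_end + config.isolation_bp
                for b_start, b_end in blocked_by_chrom[chrom]
            ):
                continue
            ref = seq[pos - 1]
            alt_choices = [b for b in BASES if b != ref]
            alt = alt_choices[int(rng.integers(3))]
            if rng.random() < config.af_common_fraction:
                pop_af = float(rng.uniform(0.0101, 0.5))
                origin = "common-AF"
            else:
                pop_af = None if rng.random() < 0.5 else float(rng.uniform(0.0, 0.01))
                origin = "background"
            records.append(
                SNVRecord(
                    cell_line_id=cell,
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    context5=seq[pos - 2],
                    context3=seq[pos],
                    pop_af=pop_af,
                )
            )
            occupied.add((chrom, pos))
            origins[(cell, chrom, pos)] = origin
            placed_bg += 1

        records.sort(key=lambda r: (r.chrom, r.pos))
        catalogs[cell] = records

    return catalogs, CatalogTruth(planted=planted_truth, origins=origins)


def write_vcf(
    records: Sequence[SNVRecord],
    path: str | Path,
    chromosomes: Mapping[str, int] | None = None,
) -> None:
    """Write one cell line's records as a minimal uncompressed VCFv4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">\n'
        )
        if chromosomes:
            for chrom, length in chromosomes.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info = "." if r.pop_af is None else f"AF={r.pop_af:.6g}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n"
            )


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def _latent_to_spearman_r(rho_s: float) -> float:
    """Latent Gaussian correlation r giving Spearman rho_s under a Gaussian
    copula: rho_s = (6/pi) * arcsin(r/2)  =>  r = 2 sin(pi * rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Map values to standard-normal scores through their ranks (a strictly
    monotone transform, so Spearman correlations are preserved)."""
    from scipy import stats

    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.5) / len(x))


def simulate_phenotypes(
    config: SimulationConfig,
) -> tuple[ExpressionTable, DrugResponseTable, dict[str, str], PhenotypeTruth]:
    """Generate expression, drug-response and category tables.

    Expression follows each gene's configured model.  An associated drug's
    log10(IC50) is a monotone (normal-scores) function of its partner
    variable plus Gaussian noise, with the latent correlation solved from
    the Gaussian-copula closed form so the population Spearman correlation
    equals the target; unassociated drugs are independent.  Associations
    scoped to one category only apply within that category's cell lines.
    """
    rng = config.rng(PHENOTYPE_STREAM)
    cells = config.cell_line_ids
    cat_map = config.category_map()
    n = len(cells)

    expr_cols: dict[str, np.ndarray] = {}
    for gene in sorted(config.expression_models):
        model = config.expression_models[gene]
        if model.kind == "normal":
            values = rng.normal(model.means[0], model.sds[0], size=n)
        else:
            low = rng.random(n) < model.weight_low
            values = np.where(
                low,
                rng.normal(model.means[0], model.sds[0], size=n),
                rng.normal(model.means[1], model.sds[1], size=n),
            )
        expr_cols[gene] = values
    expression = ExpressionTable(
        values=pd.DataFrame(expr_cols, index=pd.Index(cells, name="cell_line")),
        provenance={g: "direct" for g in expr_cols},
    )

    drugs = [f"drug{i + 1:02d}" for i in range(config.n_drugs)]
    assoc_by_drug: dict[str, AssocSpec] = {}
    for a in config.planted_assoc:
        if a.drug not in drugs:
            raise ValueError(f"association references unknown drug {a.drug!r}")
        if a.variable not in expr_cols:
            raise ValueError(f"association references unknown variable {a.variable!r}")
        if a.drug in assoc_by_drug:
            raise ValueError(f"drug {a.drug!r} has two planted associations")
        assoc_by_drug[a.drug] = a

    drug_cols: dict[str, np.ndarray] = {}
    for drug in drugs:
        base = rng.normal(0.5, 0.8, size=n)  # independent log10(IC50)
        a = assoc_by_drug.get(drug)
        if a is not None:
            mask = (
                np.ones(n, dtype=bool)
                if a.stratum == PAN_CANCER
                else np.array([cat_map[c] == a.stratum for c in cells])
            )
            if mask.sum() >= 3:
                r = _latent_to_spearman_r(a.rho)
                z = _normal_scores(expr_cols[a.variable][mask])
                eps = rng.standard_normal(int(mask.sum()))
                latent = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * eps
                base = base.copy()
                base[mask] = 0.5 + 0.8 * latent
        drug_cols[drug] = base
    response = DrugResponseTable(
        values=pd.DataFrame(drug_cols, index=pd.Index(cells, name="cell_line")),
        dialects={d: "log10" for d in drugs},
    )
    return expression, response, cat_map, PhenotypeTruth(list(config.planted_assoc))
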