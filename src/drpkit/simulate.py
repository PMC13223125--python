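"""Synthetic cohorts with planted, recoverable signal.

Everything the pipeline consumes can be generated here in silico: a cell
line-drug response cohort whose labels follow a planted logistic
mechanism, gene sequences carrying planted structural events (insertion,
deletion, inversion, mirror, duplication), a small drug set of valid
SMILES, gene-set collections in which the planted causal genes form one
over-represented set, and dose-response viability plates generated from
the 4PL model.

The generative mechanism for drug response: each cell line carries a
latent pathway activity z ~ N(0,1); expression of the causal genes is
correlated with z; mutation probability of causal genes increases with z;
each drug annotates a few causal genes as targets. The response score is

    s_ij = effect_size * z_i * match_ij

with ``match_ij`` = 1 when the drug targets an altered gene of the cell
line and a smaller baseline otherwise, and

    log10(IC50_ij) = mu0 - s_ij + eps,  eps ~ N(0, noise_sd),

with ``mu0`` calibrated so that thresholding IC50 at 1 uM yields the
configured sensitive prevalence. Thresholded labels therefore follow a
logistic-type model in the causal-gene signal and the score -> IC50
relationship is monotone and recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import CellLine, Cohort, Drug, ResponseRecord

EVENT_KINDS = ("insertion", "deletion", "inversion", "mirror", "duplication")

BASES = np.array(list("ACGT"))

#: Small embedded set of valid SMILES used as the synthetic drug library.
DRUG_SMILES = [
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("acetic acid", "CC(=O)O"),
    ("acetone", "CC(C)=O"),
    ("urea", "NC(N)=O"),
    ("glycine", "NCC(=O)O"),
    ("pyridine", "c1ccncc1"),
    ("pyrimidine", "c1cncnc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("cyclohexane", "C1CCCCC1"),
    ("benzoic acid", "O=C(O)c1ccccc1"),
    ("anisole", "COc1ccccc1"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give a 1,000-pair cohort (100 cell lines x 10 drugs) with 10
    planted causal genes out of 100, a strong planted effect and moderate
    log10-IC50 noise -- large enough for the planted signal to be
    recoverable by the pipeline, small enough for desk-scale runs.
    """

    n_cell_lines: int = 100
    n_genes: int = 100
    n_drugs: int = 10
    prevalence: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 0.3
    planted_causal_genes: int = 10
    seed: int = 0
    # secondary knobs
    expression_loading: float = 0.9
    baseline_match: float = 0.3
    targets_per_drug: int = 3
    sequence_length: int = 160
    events_per_gene: int = 2
    event_length: int = 10

    def __post_init__(self) -> None:
        for name in ("n_cell_lines", "n_genes", "n_drugs", "planted_causal_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be nonnegative")
        if self.planted_causal_genes > self.n_genes:
            raise ValueError("more causal genes than genes")


@dataclass
class PlannedEvent:
    kind: str
    position: int  # 0-based position in the reference sequence
    length: int
    payload: Optional[str] = None  # inserted subsequence, for insertions

    def span(self) -> tuple[int, int]:
        """Occupied half-open interval in reference coordinates."""
        if self.kind == "insertion":
            return (self.position, self.position)
        return (self.position, self.position + self.length)


@dataclass
class GroundTruth:
    causal_gene_ids: list[str]
    logistic_coefficients: np.ndarray
    planted_events_per_gene: dict[str, list[PlannedEvent]] = field(
        default_factory=dict
    )
    latent_activity: Optional[np.ndarray] = None
    target_match: Optional[np.ndarray] = None


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def mutate_sequences(
    references: Mapping[str, str],
    plans: Mapping[str, Sequence[PlannedEvent]],
) -> dict[str, str]:
    """Apply planned structural events to reference sequences.

    Events for one sequence must not overlap in reference coordinates;
    overlapping plans raise, keeping the ground truth unambiguous. Events
    are applied right-to-left so reference positions stay valid.
    """
    out: dict[str, str] = {}
    for name, ref in references.items():
        events = sorted(plans.get(name, ()), key=lambda e: e.position)
        last_end = -1
        for ev in events:
            start, end = ev.span()
            if ev.kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {ev.kind!r}")
            if start < last_end or end > len(ref):
                raise ValueError(
                    f"overlapping or out-of-bounds event {ev.kind} at "
                    f"{ev.position} in {name}"
                )
            last_end = max(last_end, end if end > start else start + 1)
        seq = ref
        for ev in reversed(events):
            p, n = ev.position, ev.length
            segment = ref[p : p + n]
            if ev.kind == "insertion":
                if not ev.payload:
                    raise ValueError("insertion requires a payload")
                seq = seq[:p] + ev.payload + seq[p:]
            elif ev.kind == "deletion":
                seq = seq[:p] + seq[p + n :]
            elif ev.kind == "duplication":
                seq = seq[: p + n] + segment + seq[p + n :]
            elif ev.kind == "inversion":
                seq = seq[:p] + segment[::-1] + seq[p + n :]
            elif ev.kind == "mirror":
                half = segment[: (n + 1) // 2]
                pal = half + half[: n // 2][::-1]
                seq = seq[:p] + pal + seq[p + n :]
        out[name] = seq
    return out


def plan_events(
    rng: np.random.Generator,
    seq_length: int,
    n_events: int,
    event_length: int,
) -> list[PlannedEvent]:
    """Draw non-overlapping events, one kind each, at spaced positions."""
    gap = event_length + 4
    max_events = max(0, (seq_length - event_length) // gap)
    n_events = min(n_events, max_events)
    starts = rng.choice(max_events, size=n_events, replace=False) * gap
    events = []
    for start in np.sort(starts):
        kind = str(rng.choice(EVENT_KINDS))
        payload = None
        if kind == "insertion":
            payload = _random_sequence(rng, event_length)
        events.append(
            PlannedEvent(kind, int(start), event_length, payload=payload)
        )
    return events


def generate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a labeled cohort plus the ground truth of its planted signal.

    Identical seeds reproduce byte-identical cohorts. Raises if the
    thresholded labels degenerate to a single class.
    """
    rng = np.random.default_rng(config.seed)
    nc, ng, nd = config.n_cell_lines, config.n_genes, config.n_drugs

    genes = [f"G{k:04d}" for k in range(ng)]
    causal_idx = np.sort(
        rng.choice(ng, size=config.planted_causal_genes, replace=False)
    )
    causal = [genes[i] for i in causal_idx]

    z = rng.standard_normal(nc)

    load = config.expression_loading
    expr = rng.standard_normal((ng, nc))
    expr[causal_idx] = load * z + np.sqrt(1 - load**2) * expr[causal_idx]

    mut_p = np.full((ng, nc), 0.08)
    mut_p[causal_idx] = 1.0 / (1.0 + np.exp(-1.5 * z))
    mutation = (rng.uniform(size=(ng, nc)) < mut_p).astype(float)

    cnv = 0.5 * rng.standard_normal((ng, nc))

    cell_lines = {
        f"CL{i:04d}": CellLine(
            id=f"CL{i:04d}",
            lineage=f"lineage{i % 4}",
            mutation_calls=mutation[:, i].copy(),
            cnv=cnv[:, i].copy(),
            expression=expr[:, i].copy(),
        )
        for i in range(nc)
    }

    drugs = {}
    for j in range(nd):
        name, smiles = DRUG_SMILES[j % len(DRUG_SMILES)]
        targets = [
            causal[(j * config.targets_per_drug + t) % len(causal)]
            for t in range(config.targets_per_drug)
        ]
        drugs[f"D{j:03d}"] = Drug(
            id=f"D{j:03d}", name=name, targets=sorted(set(targets)),
            smiles=smiles,
        )

    # drug-target match: 1 if any annotated target is mutated, else baseline
    gene_pos = {g: k for k, g in enumerate(genes)}
    match = np.full((nc, nd), config.baseline_match)
    for j, drug in enumerate(drugs.values()):
        tgt_rows = [gene_pos[t] for t in drug.targets]
        hit = mutation[tgt_rows, :].max(axis=0) > 0
        match[hit, j] = 1.0

    score = config.effect_size * z[:, None] * match
    eps = config.noise_sd * rng.standard_normal((nc, nd))
    decision = score - eps
    mu0 = float(np.quantile(decision, 1.0 - config.prevalence))
    log_ic50 = mu0 - score + eps
    ic50 = np.power(10.0, log_ic50)

    labels_sensitive = ic50 < 1.0
    if labels_sensitive.all() or not labels_sensitive.any():
        raise ValueError(
            "degenerate configuration: thresholded labels are single-class"
        )

    responses = [
        ResponseRecord(
            cell_line_id=f"CL{i:04d}",
            drug_id=f"D{j:03d}",
            ic50_uM=float(ic50[i, j]),
        )
        for i in range(nc)
        for j in range(nd)
    ]

    references = {g: _random_sequence(rng, config.sequence_length) for g in genes}
    plans = {
        g: plan_events(
            rng, config.sequence_length, config.events_per_gene,
            config.event_length,
        )
        for g in genes
    }
    variants = mutate_sequences(references, plans)

    coeffs = np.zeros(ng)
    coeffs[causal_idx] = config.effect_size * load

    cohort = Cohort(
        cell_lines=cell_lines,
        drugs=drugs,
        responses=responses,
        genes=genes,
        sequences=variants,
        reference_sequences=references,
    )
    truth = GroundTruth(
        causal_gene_ids=causal,
        logistic_coefficients=coeffs,
        planted_events_per_gene=plans,
        latent_activity=z,
        target_match=match,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Dose-response plates
# ---------------------------------------------------------------------------

#: Seven-point concentration grid (uM) used throughout.
DEFAULT_CONCENTRATIONS = (0.01, 0.032, 0.1, 0.32, 1.0, 3.2, 10.0)


def four_pl(c: np.ndarray, ic50: float, hill: float, bottom: float,
            top: float = 100.0) -> np.ndarray:
    """4PL viability curve with the pharmacology sign convention.

    v(c) = B + (T - B) / (1 + (c / IC50)^(-h)), so a negative Hill slope
    h gives a decreasing sigmoid: v -> T as c -> 0, v -> B as c -> inf,
    and v(IC50) = (T + B) / 2.
    """
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.power(c / ic50, -hill))


def generate_plate(
    ic50_uM: float,
    hill: float,
    bottom: float = 0.0,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> "pd.DataFrame":
    """Long-format viability table from a 4PL curve plus Gaussian noise.

    Columns: concentration_uM, replicate, viability_pct. Noiseless when
    ``noise_sd`` is zero. Hill slopes are conventionally negative for
    inhibitory dose-response (viability falls with concentration).
    """
    import pandas as pd

    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any() or (np.diff(conc) <= 0).any():
        raise ValueError("concentrations must be positive and increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        v = four_pl(conc, ic50_uM, hill, bottom)
        if noise_sd > 0:
            v = v + noise_sd * rng.standard_normal(conc.size)
        for c, vi in zip(conc, v):
            rows.append(
                {"concentration_uM": c, "replicate": rep, "viability_pct": vi}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def make_genesets(
    truth: GroundTruth,
    genes: Sequence[str],
    n_decoy_sets: int = 9,
    set_size: int = 10,
    seed: int = 0,
) -> dict[str, tuple[str, list[str]]]:
    """Gene-set collection in which the planted causal set is one entry.

    Decoy sets are random draws from the gene universe; the causal set is
    the planted causal genes, so over-representation of a causal-derived
    list is recoverable end-to-end.
    """
    # dedicated stream: a bare seed would replay the cohort generator's
    # first draw and make decoy 0 identical to the causal set
    rng = np.random.default_rng([seed, 0x6E5E75])
    sets = {"PLANTED_CAUSAL": ("planted causal pathway", list(truth.causal_gene_ids))}
    pool = np.array(genes)
    for s in range(n_decoy_sets):
        members = rng.choice(pool, size=min(set_size, len(pool)), replace=False)
        sets[f"DECOY_{s:02d}"] = ("random decoy set", sorted(members.tolist()))
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Sequence[str]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Curation fixture with planted exclusion counts
# ---------------------------------------------------------------------------


def planted_curation_cohort(
    initial: int = 8146,
    exclusions: tuple[int, int, int] = (854, 4179, 499),
    seed: int = 0,
) -> Cohort:
    """Raw cohort engineered so curation excludes exactly the given counts.

    The three exclusion groups are planted on dedicated entities: records
    with missing IC50, records referencing cell lines with an absent
    expression block, and records referencing drugs without SMILES/InChI.
    """
    e1, e2, e3 = exclusions
    n_good = initial - e1 - e2 - e3
    if n_good <= 0:
        raise ValueError("exclusions exceed initial cohort size")
    rng = np.random.default_rng(seed)
    genes = ["G0", "G1", "G2"]

    def profile() -> dict:
        return {
            "mutation_calls": (rng.uniform(size=3) < 0.5).astype(float),
            "cnv": rng.standard_normal(3),
            "expression": rng.standard_normal(3),
        }

    cohort = Cohort(genes=genes)

    n_cells = max(1, int(np.ceil(np.sqrt(n_good))))
    n_drugs = int(np.ceil(n_good / n_cells))
    for i in range(n_cells):
        cid = f"GC{i:04d}"
        cohort.cell_lines[cid] = CellLine(id=cid, **profile())
    for j in range(n_drugs + int(np.ceil(e1 / n_cells))):
        did = f"GD{j:04d}"
        cohort.drugs[did] = Drug(id=did, name=did, smiles="CCO")

    pairs = [
        (f"GC{i:04d}", f"GD{j:04d}")
        for j in range(n_drugs + int(np.ceil(e1 / n_cells)))
        for i in range(n_cells)
    ]
    good_pairs = pairs[:n_good]
    missing_pairs = pairs[n_good : n_good + e1]

    for c, d in good_pairs:
        cohort.responses.append(ResponseRecord(c, d, ic50_uM=0.5))
    for c, d in missing_pairs:
        cohort.responses.append(ResponseRecord(c, d, ic50_uM=None))

    # incomplete molecular profiles: expression block absent
    n_badcl = max(1, int(np.ceil(e2 / max(1, n_drugs))))
    for i in range(n_badcl):
        cid = f"BC{i:04d}"
        prof = profile()
        prof["expression"] = None
        cohort.cell_lines[cid] = CellLine(id=cid, **prof)
    count = 0
    for i in range(n_badcl):
        for j in range(n_drugs):
            if count == e2:
                break
            cohort.responses.append(
                ResponseRecord(f"BC{i:04d}", f"GD{j:04d}", ic50_uM=0.5)
            )
            count += 1

    # drugs without structure
    n_baddr = max(1, int(np.ceil(e3 / n_cells)))
    for j in range(n_baddr):
        did = f"BD{j:04d}"
        cohort.drugs[did] = Drug(id=did, name=did, smiles="", inchi="")
    count = 0
    for j in range(n_baddr):
        for i in range(n_cells):
            if count == e3:
                break
            cohort.responses.append(
                ResponseRecord(f"GC{i:04d}", f"BD{j:04d}", ic50_uM=0.5)
            )
            count += 1

    return cohort
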