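"""Synthetic cohorts and drug-signature libraries with full ground truth.

The generator emulates a whole-blood RNA-seq case/control cohort in which
disease heterogeneity is driven by gene modules: disjoint blocks of genes
share an endotype-specific activation (a log2 shift applied to every patient
of that endotype) plus a per-module latent sample factor, so that module
genes are co-expressed both between and within patient groups.  Counts are
negative binomial with a shared dispersion (variance mu + dispersion * mu^2)
and lognormal per-sample library-size factors.

The companion drug-library generator plants, for each endotype, "reverser"
signatures whose log2 fold changes oppose the endotype's differential
signature on its top genes, alongside neutral pure-noise signatures; the
truth map records every signature's intended target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import as_rng

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "DrugLibrarySpec",
    "SyntheticDrugLibrary",
    "generate_cohort",
    "generate_drug_library",
    "paper_default",
]

#: log2 sd of the per-module latent sample factor inducing within-group
#: co-expression of module genes
MODULE_LATENT_SD = 0.3

#: log2 sd of neutral (non-reverser) drug-signature fold changes
NEUTRAL_LOG2FC_SD = 1.0

# Endotype x module activation (log2 units) for the default preset.  Each
# endotype has a disjoint two-sided fingerprint: one over-expressed primary
# module (m1-m5) and, for four of the five endotypes, one under-expressed
# secondary module (m6-m9); the smallest endotype (E4, ~9% of patients)
# carries a single strong neutrophil-like primary instead.  Amplitudes are
# size-compensated so every module's between-sample activation variance
# (a^2 p (1-p)) is comparable, keeping all nine modules detectable, and no
# gene is moved by more than one endotype, so differential signatures - and
# hence planted drug reversers - are endotype-exclusive.
_DEFAULT_ACTIVATION = np.array(
    [
        # m1   m2   m3   m4   m5    m6    m7    m8    m9
        [2.0, 0.0, 0.0, 0.0, 0.0, -2.0, 0.0, 0.0, 0.0],
        [0.0, 2.0, 0.0, 0.0, 0.0, 0.0, -2.0, 0.0, 0.0],
        [0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 0.0, -2.0, 0.0],
        [0.0, 0.0, 0.0, 3.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 2.5, 0.0, 0.0, 0.0, -2.2],
    ]
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic case/control cohort."""

    n_patients: int = 120
    n_controls: int = 58
    n_genes: int = 15000
    n_modules: int = 9
    module_sizes: tuple = (300, 250, 220, 200, 180, 150, 120, 100, 80)
    n_endotypes: int = 5
    endotype_proportions: tuple = (0.242, 0.267, 0.25, 0.091, 0.15)
    activation: np.ndarray = field(
        default_factory=lambda: _DEFAULT_ACTIVATION.copy()
    )
    baseline_log_mean_range: tuple = (3.0, 9.0)
    dispersion: float = 0.1
    library_size_lognormal: tuple = (0.0, 0.2)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "n_controls", "n_genes", "n_modules", "n_endotypes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        props = np.asarray(self.endotype_proportions, dtype=float)
        if props.size != self.n_endotypes or abs(props.sum() - 1.0) > 1e-9 or (props <= 0).any():
            raise ValueError(
                "endotype_proportions must be positive and sum to 1: "
                f"got {self.endotype_proportions}"
            )
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        act = np.asarray(self.activation, dtype=float)
        if act.shape != (self.n_endotypes, self.n_modules):
            raise ValueError(
                f"activation must be {self.n_endotypes} x {self.n_modules}, got {act.shape}"
            )


def paper_default(seed: int = 0, **overrides) -> CohortSpec:
    """The "paper-default" preset: 120 SLE patients, 58 controls, 15,000
    genes, 9 planted modules, 5 endotypes with the default activation map."""
    return replace(CohortSpec(seed=seed), **overrides)


def small(seed: int = 0, **overrides) -> CohortSpec:
    """A down-scaled cohort (60 samples, 1,500 genes) with the same module
    and endotype structure, for quick smoke runs."""
    base = CohortSpec(
        n_patients=40,
        n_controls=20,
        n_genes=1500,
        module_sizes=(60, 50, 44, 40, 36, 30, 24, 20, 16),
        seed=seed,
    )
    return replace(base, **overrides)


PRESETS = {"paper-default": paper_default, "small": small}


@dataclass
class SyntheticCohort:
    """Counts plus ground truth for a generated cohort."""

    counts: pd.DataFrame  # gene x sample integers
    sample_meta: pd.DataFrame  # sample_id, status, true_endotype
    gene_truth: pd.Series  # gene -> module name or "background"
    spec: CohortSpec

    @property
    def patients(self) -> list:
        return list(self.sample_meta.loc[self.sample_meta.status == "SLE", "sample_id"])

    @property
    def controls(self) -> list:
        return list(
            self.sample_meta.loc[self.sample_meta.status == "control", "sample_id"]
        )


def _largest_remainder_counts(n: int, props: np.ndarray) -> np.ndarray:
    raw = props * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from the spec's negative-binomial module model.

    Gene g of sample s has NB mean
    ``2 ** (baseline_g + activation[e, m] + latent[m, s]) * libsize_s``
    where m is g's planted module (background genes have no activation or
    latent term) and e is the sample's endotype (controls contribute
    activation 0).  Deterministic for a fixed spec seed.
    """
    spec.validate()
    rng = as_rng(spec.seed)
    n_genes, n_mod = spec.n_genes, spec.n_modules
    n_samples = spec.n_patients + spec.n_controls

    gene_ids = [f"gene{str(i + 1).zfill(5)}" for i in range(n_genes)]
    module_names = [f"m{j + 1}" for j in range(n_mod)]
    truth = np.array(["background"] * n_genes, dtype=object)
    start = 0
    for j, size in enumerate(spec.module_sizes):
        truth[start : start + size] = module_names[j]
        start += size

    patient_ids = [f"P{str(i + 1).zfill(3)}" for i in range(spec.n_patients)]
    control_ids = [f"C{str(i + 1).zfill(3)}" for i in range(spec.n_controls)]
    sample_ids = patient_ids + control_ids

    group_sizes = _largest_remainder_counts(
        spec.n_patients, np.asarray(spec.endotype_proportions, dtype=float)
    )
    endo_labels = np.repeat(np.arange(spec.n_endotypes), group_sizes)
    rng.shuffle(endo_labels)

    baseline = rng.uniform(*spec.baseline_log_mean_range, size=n_genes)
    latent = rng.normal(0.0, MODULE_LATENT_SD, size=(n_mod, n_samples))
    log_lib = rng.normal(*spec.library_size_lognormal, size=n_samples)
    lib = np.exp(log_lib)

    act = np.asarray(spec.activation, dtype=float)
    log2mu = np.tile(baseline[:, None], (1, n_samples))
    start = 0
    for j, size in enumerate(spec.module_sizes):
        rows = slice(start, start + size)
        shift = latent[j].copy()
        shift[: spec.n_patients] += act[endo_labels, j]
        log2mu[rows] += shift[None, :]
        start += size

    mu = (2.0**log2mu) * lib[None, :]
    r = 1.0 / spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": ["SLE"] * spec.n_patients + ["control"] * spec.n_controls,
            "true_endotype": [f"E{e + 1}" for e in endo_labels]
            + [pd.NA] * spec.n_controls,
        }
    )
    return SyntheticCohort(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        sample_meta=meta,
        gene_truth=pd.Series(truth, index=gene_ids, name="module"),
        spec=spec,
    )


@dataclass(frozen=True)
class DrugLibrarySpec:
    """Parameters of a synthetic drug-signature library."""

    n_drugs: int = 40
    genes_per_signature: int = 400
    n_reversers_per_endotype: int = 2
    reversal_effect: float = 2.0
    noise_sd: float = 0.2
    frac_significant: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.genes_per_signature < 301:
            raise ValueError("genes_per_signature must be >= 301")
        if self.n_reversers_per_endotype < 1:
            raise ValueError("n_reversers_per_endotype must be >= 1")
        if not (0 < self.frac_significant <= 1):
            raise ValueError("frac_significant must be in (0, 1]")
        if self.reversal_effect <= 0:
            raise ValueError("reversal_effect must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticDrugLibrary:
    """Long-format signature table plus the signature -> target truth map."""

    signatures: pd.DataFrame  # signature_id, source, gene, log2fc, pvalue
    truth: dict  # signature_id -> endotype name or "neutral"


def generate_drug_library(
    spec: DrugLibrarySpec, endotype_signatures: dict[str, pd.DataFrame]
) -> SyntheticDrugLibrary:
    """Plant reverser and neutral drug signatures against endotype DE results.

    Parameters
    ----------
    endotype_signatures : dict
        Endotype name -> DE table as returned by :func:`moltax.diffexp.de_test`
        (needs ``log2fc`` and ``wald`` columns indexed by gene).

    A reverser for endotype e takes e's ``genes_per_signature`` top genes by
    |wald| and sets log2fc to the negated endotype log2fc rescaled so the
    mean |log2fc| equals ``reversal_effect``, plus N(0, noise_sd) noise --
    i.e. an exact anti-signature at noise_sd = 0.  Neutral drugs draw genes
    at random from the tested universe with N(0, 1) log2fc.  Exactly ``round(frac_significant * n)`` rows per
    signature get p-values below 0.05 (assigned to the largest |log2fc|
    rows); the rest are uniform on (0.05, 1].
    """
    spec.validate()
    if not endotype_signatures:
        raise ValueError("at least one endotype signature is required")
    for name, sig in endotype_signatures.items():
        if sig is None or len(sig) == 0:
            raise ValueError(f"endotype signature {name!r} is empty")
    rng = as_rng(spec.seed)

    endos = list(endotype_signatures)
    n_rev_total = spec.n_reversers_per_endotype * len(endos)
    if spec.n_drugs < n_rev_total:
        raise ValueError(
            f"n_drugs={spec.n_drugs} cannot hold "
            f"{n_rev_total} reversers ({spec.n_reversers_per_endotype} per endotype)"
        )
    universe = sorted(
        set().union(*(set(sig.index) for sig in endotype_signatures.values()))
    )

    records = []
    truth: dict[str, str] = {}
    drug_idx = 0

    def _pvalues(log2fc: np.ndarray) -> np.ndarray:
        n = log2fc.size
        n_sig = int(round(spec.frac_significant * n))
        p = rng.uniform(0.05, 1.0, size=n)
        p[p == 0.05] = np.nextafter(0.05, 1.0)  # keep strictly above alpha
        order = np.lexsort((np.arange(n), -np.abs(log2fc)))
        sig_rows = order[:n_sig]
        p[sig_rows] = np.maximum(rng.uniform(0.0, 0.05, size=n_sig), 1e-12)
        return p

    for endo in endos:
        de = endotype_signatures[endo]
        de = de.loc[de["wald"].notna()]
        top = de.reindex(de["wald"].abs().sort_values(ascending=False).index)
        top = top.iloc[: spec.genes_per_signature]
        if len(top) < spec.genes_per_signature:
            raise ValueError(
                f"endotype {endo!r} has only {len(top)} tested genes; "
                f"needs {spec.genes_per_signature}"
            )
        for _ in range(spec.n_reversers_per_endotype):
            drug_idx += 1
            sig_id = f"drug{str(drug_idx).zfill(3)}"
            x = top["log2fc"].to_numpy()
            scale = np.mean(np.abs(x))
            fc = -spec.reversal_effect * x / (scale if scale > 0 else 1.0)
            if spec.noise_sd:
                fc = fc + rng.normal(0.0, spec.noise_sd, size=fc.size)
            records.append(
                pd.DataFrame(
                    {
                        "signature_id": sig_id,
                        "source": "LINCSCP",
                        "gene": top.index.to_numpy(),
                        "log2fc": fc,
                        "pvalue": _pvalues(np.asarray(fc, dtype=float)),
                    }
                )
            )
            truth[sig_id] = endo

    while drug_idx < spec.n_drugs:
        drug_idx += 1
        sig_id = f"drug{str(drug_idx).zfill(3)}"
        genes = rng.choice(universe, size=spec.genes_per_signature, replace=False)
        fc = rng.normal(0.0, NEUTRAL_LOG2FC_SD, size=spec.genes_per_signature)
        records.append(
            pd.DataFrame(
                {
                    "signature_id": sig_id,
                    "source": "CMAP",
                    "gene": genes,
                    "log2fc": fc,
                    "pvalue": _pvalues(fc),
                }
            )
        )
        truth[sig_id] = "neutral"

    return SyntheticDrugLibrary(
        signatures=pd.concat(records, ignore_index=True), truth=truth
    )
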