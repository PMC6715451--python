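"""Synthetic fixtures with planted ground truth.

Every downstream stage of the pipeline (re-annotation, differential
expression, shared-RBP network extraction, biclustering, co-expression
modules, clinical statistics) is exercised on data produced here, so each
generator co-emits the truth it planted: which transcripts are
differentially expressed, which belong to the co-regulated block, which
lncRNA is the hub, and which probes survive the re-annotation rules.

The default configuration emulates the statistical shape of a small
two-tissue microarray study of insulin resistance: 10 cases vs 13 controls
(plus a paired before/after-treatment arm on the cases), ~200 lncRNAs and
~2000 mRNAs on a log2 scale, and a bipartite RBP-binding structure over a
few dozen RNA-binding proteins in which one planted block of transcripts
shares the hub lncRNA's binding partners far above background.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import ExpressionDataset, LNCRNA, MRNA
from .reannotation import ProbeTranscriptMap


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Counts are feature/sample numbers; ``effect_size`` and ``noise_sd`` are
    in log2 expression units; the two binding probabilities control the
    bipartite RBP structure (within-block sharing must exceed background).
    """

    n_lncrna: int = 200
    n_mrna: int = 2000
    n_rbp: int = 30
    n_case: int = 10
    n_control: int = 13
    n_de_lncrna: int = 12
    n_de_mrna: int = 50
    effect_size: float = 2.0
    noise_sd: float = 0.5
    block_size: int = 40
    block_n_lncrna: int = 6
    block_rbp_overlap: float = 0.9
    background_binding_prob: float = 0.1
    # the hub binds each RBP with hub_binding_frac * block_rbp_overlap: its
    # repertoire must stay well below the whole RBP universe, otherwise
    # sharing it is expected by chance and no tail can be significant
    hub_binding_frac: float = 1 / 3
    # latent-factor loadings of block members (shared-factor co-expression)
    block_loading_range: tuple[float, float] = (0.6, 0.9)
    treated_fraction: float = 0.8
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    # clinical cohort
    n_pcos_subjects: int = 52
    n_control_subjects: int = 42
    clinical_effect: float = 1.0
    seed: int = 42

    def validate(self) -> None:
        counts = dict(
            n_lncrna=self.n_lncrna, n_mrna=self.n_mrna, n_rbp=self.n_rbp,
            n_case=self.n_case, n_control=self.n_control,
            n_de_lncrna=self.n_de_lncrna, n_de_mrna=self.n_de_mrna,
            block_size=self.block_size, block_n_lncrna=self.block_n_lncrna,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_case < 3 or self.n_control < 3:
            raise ValueError("need at least 3 samples per group")
        for name in ("block_rbp_overlap", "background_binding_prob",
                     "treated_fraction", "clinical_effect", "hub_binding_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.block_rbp_overlap <= self.background_binding_prob:
            raise ValueError("block_rbp_overlap must exceed background_binding_prob")
        if self.block_n_lncrna > self.n_de_lncrna or self.block_n_lncrna >= self.block_size:
            raise ValueError("block_n_lncrna must fit inside DE lncRNAs and the block")
        if self.block_size - self.block_n_lncrna > self.n_de_mrna:
            raise ValueError("block mRNAs must fit inside the DE mRNA set")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    # feature-id layout (deterministic, independent of the rng)
    def lncrna_ids(self) -> list[str]:
        return [f"LNC{i:04d}" for i in range(1, self.n_lncrna + 1)]

    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i:04d}" for i in range(1, self.n_mrna + 1)]

    def rbp_ids(self) -> list[str]:
        return [f"RBP{i:02d}" for i in range(1, self.n_rbp + 1)]


@dataclass
class PlantedTruth:
    """Ground truth co-emitted with every fixture."""

    de_features: dict[str, set[str]]          # contrast name -> feature ids
    block_members: set[str]
    hub_lncrna: str
    module_trait_cor: float

    def __post_init__(self) -> None:
        if self.hub_lncrna not in self.block_members:
            raise ValueError("hub lncRNA must be a block member")

    def to_json(self) -> str:
        payload = {
            "de_features": {k: sorted(v) for k, v in self.de_features.items()},
            "block_members": sorted(self.block_members),
            "hub_lncrna": self.hub_lncrna,
            "module_trait_cor": self.module_trait_cor,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            de_features={k: set(v) for k, v in d["de_features"].items()},
            block_members=set(d["block_members"]),
            hub_lncrna=d["hub_lncrna"],
            module_trait_cor=d["module_trait_cor"],
        )


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def planted_truth(cfg: SyntheticConfig) -> PlantedTruth:
    """Deterministic layout of DE features, block members and the hub.

    The block occupies the first ``block_n_lncrna`` lncRNAs and the first
    ``block_size - block_n_lncrna`` mRNAs; DE sets extend the block.  The
    paired (treated) DE set is the block plus a ``treated_fraction`` prefix
    of the remaining DE features, so the two contrasts intersect exactly in
    the treated set.
    """
    cfg.validate()
    lnc, mrna = cfg.lncrna_ids(), cfg.mrna_ids()
    block_lnc = lnc[: cfg.block_n_lncrna]
    block_mrna = mrna[: cfg.block_size - cfg.block_n_lncrna]
    block = set(block_lnc) | set(block_mrna)
    de_lnc = lnc[: cfg.n_de_lncrna]
    de_mrna = mrna[: cfg.n_de_mrna]
    de1 = set(de_lnc) | set(de_mrna)

    extra_lnc = [f for f in de_lnc if f not in block]
    extra_mrna = [f for f in de_mrna if f not in block]
    n_tl = round(cfg.treated_fraction * len(extra_lnc))
    n_tm = round(cfg.treated_fraction * len(extra_mrna))
    treated = block | set(extra_lnc[:n_tl]) | set(extra_mrna[:n_tm])

    # theoretical point-biserial correlation of a block member with the
    # case/control label (group shift + latent + noise variance)
    p = cfg.n_case / (cfg.n_case + cfg.n_control)
    load2 = float(np.mean(np.array(cfg.block_loading_range) ** 2))
    var_tot = cfg.effect_size**2 * p * (1 - p) + load2 + cfg.noise_sd**2
    r_pb = cfg.effect_size * math.sqrt(p * (1 - p)) / math.sqrt(var_tot)

    return PlantedTruth(
        de_features={"case_control": de1, "paired": treated},
        block_members=block,
        hub_lncrna=block_lnc[0],
        module_trait_cor=r_pb,
    )


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

def generate_interaction_tables(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Bipartite lncRNA-RBP and mRNA-RBP binding tables.

    Background features bind each RBP independently with
    ``background_binding_prob``.  The hub lncRNA binds each RBP with
    ``hub_binding_frac * block_rbp_overlap``; every other block member
    includes each hub RBP with probability ``block_rbp_overlap`` and
    non-hub RBPs at background rate, so sharing inside the block is
    enriched far above background while the hub's repertoire stays a
    minority of the RBP universe.
    """
    cfg.validate()
    truth = planted_truth(cfg)
    rng = _rng(cfg, stream=1)
    rbps = np.array(cfg.rbp_ids())

    hub_mask = rng.random(cfg.n_rbp) < cfg.hub_binding_frac * cfg.block_rbp_overlap
    hub_set = rbps[hub_mask]

    def feature_rbps(fid: str) -> np.ndarray:
        if fid == truth.hub_lncrna:
            return hub_set
        if fid in truth.block_members:
            keep_hub = hub_mask & (rng.random(cfg.n_rbp) < cfg.block_rbp_overlap)
            keep_bg = ~hub_mask & (rng.random(cfg.n_rbp) < cfg.background_binding_prob)
            return rbps[keep_hub | keep_bg]
        return rbps[rng.random(cfg.n_rbp) < cfg.background_binding_prob]

    lnc_rows, mrna_rows = [], []
    for fid in cfg.lncrna_ids():
        lnc_rows.extend((fid, r) for r in feature_rbps(fid))
    for fid in cfg.mrna_ids():
        mrna_rows.extend((fid, r) for r in feature_rbps(fid))

    lnc_tab = pd.DataFrame(lnc_rows, columns=["feature_id", "rbp_id"])
    mrna_tab = pd.DataFrame(mrna_rows, columns=["feature_id", "rbp_id"])
    return lnc_tab, mrna_tab, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

class ExpressionBundle(NamedTuple):
    case_control: ExpressionDataset
    paired: ExpressionDataset


def generate_expression_dataset(
    cfg: SyntheticConfig, truth: PlantedTruth
) -> ExpressionBundle:
    """Two-contrast expression data with planted shifts and a block factor.

    Case/control contrast: DE features are shifted by ``effect_size`` in the
    case group (random sign per feature; block members are coherently
    upregulated); block members additionally load on a shared latent factor,
    making their pairwise correlation high.  The latent factor is centered
    within each group so it is orthogonal to the group contrast and the
    planted effect size is exactly ``effect_size``.  Paired contrast: the
    same case subjects before and after treatment, with a per-subject random
    intercept; treatment reverses the shift for the treated (paired-DE)
    subset.
    """
    cfg.validate()
    rng = _rng(cfg, stream=2)
    lnc, mrna = cfg.lncrna_ids(), cfg.mrna_ids()
    feats = lnc + mrna
    n_feat = len(feats)
    biotype = pd.Series(
        [LNCRNA] * len(lnc) + [MRNA] * len(mrna), index=feats, name="biotype"
    )

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_feat)
    de1 = np.array([f in truth.de_features["case_control"] for f in feats])
    treated = np.array([f in truth.de_features["paired"] for f in feats])
    in_block = np.array([f in truth.block_members for f in feats])
    sign = np.where(in_block, 1.0, rng.choice([-1.0, 1.0], n_feat))
    lo, hi = cfg.block_loading_range
    loading = np.where(in_block, rng.uniform(lo, hi, n_feat), 0.0)
    shift = np.where(de1, sign * cfg.effect_size, 0.0)

    def centered(n: int) -> np.ndarray:
        z = rng.standard_normal(n)
        return z - z.mean()

    # --- case/control ---------------------------------------------------
    case_cols = [f"CASE{i:02d}" for i in range(1, cfg.n_case + 1)]
    ctrl_cols = [f"CTRL{i:02d}" for i in range(1, cfg.n_control + 1)]
    cols = case_cols + ctrl_cols
    # block latent factor, centered per group (orthogonal to the contrast)
    z = np.concatenate([centered(cfg.n_case), centered(cfg.n_control)])
    is_case = np.array([1.0] * cfg.n_case + [0.0] * cfg.n_control)
    mat = (
        baseline[:, None]
        + shift[:, None] * is_case[None, :]
        + loading[:, None] * z[None, :]
        + rng.normal(0.0, cfg.noise_sd, (n_feat, len(cols)))
    )
    ds_cc = ExpressionDataset(
        matrix=pd.DataFrame(mat, index=feats, columns=cols),
        labels=pd.Series(
            ["PCOS"] * cfg.n_case + ["control"] * cfg.n_control, index=cols
        ),
        contrast=("PCOS", "control"),
        biotype=biotype,
    )

    # --- paired before/after -------------------------------------------
    subjects = [f"SUBJ{i:02d}" for i in range(1, cfg.n_case + 1)]
    before = [f"{s}_before" for s in subjects]
    after = [f"{s}_after" for s in subjects]
    pcols = before + after
    intercept = rng.normal(0.0, cfg.noise_sd, cfg.n_case)
    z_before = centered(cfg.n_case)
    z_after = centered(cfg.n_case)
    base_p = baseline[:, None] + intercept[None, :]
    mat_before = (
        base_p + shift[:, None]
        + loading[:, None] * z_before[None, :]
        + rng.normal(0.0, cfg.noise_sd, (n_feat, cfg.n_case))
    )
    reverse = np.where(treated, shift, 0.0)
    mat_after = (
        base_p + shift[:, None] - reverse[:, None]
        + loading[:, None] * z_after[None, :]
        + rng.normal(0.0, cfg.noise_sd, (n_feat, cfg.n_case))
    )
    ds_paired = ExpressionDataset(
        matrix=pd.DataFrame(
            np.hstack([mat_before, mat_after]), index=feats, columns=pcols
        ),
        labels=pd.Series(
            ["before"] * cfg.n_case + ["after"] * cfg.n_case, index=pcols
        ),
        contrast=("after", "before"),
        biotype=biotype,
        pairing=pd.Series(subjects + subjects, index=pcols),
    )
    return ExpressionBundle(ds_cc, ds_paired)


def generate_null_dataset(
    n_features: int, n_per_group: int, seed: int, noise_sd: float = 1.0
) -> ExpressionDataset:
    """Global-null two-group dataset (no planted effects) for calibration."""
    rng = np.random.default_rng(seed)
    cols = [f"A{i:02d}" for i in range(n_per_group)] + [
        f"B{i:02d}" for i in range(n_per_group)
    ]
    feats = [f"F{i:04d}" for i in range(n_features)]
    mat = rng.normal(0.0, noise_sd, (n_features, len(cols)))
    return ExpressionDataset(
        matrix=pd.DataFrame(mat, index=feats, columns=cols),
        labels=pd.Series(["case"] * n_per_group + ["control"] * n_per_group, index=cols),
        contrast=("case", "control"),
        biotype=pd.Series([MRNA] * n_features, index=feats),
    )


# ---------------------------------------------------------------------------
# probe alignments
# ---------------------------------------------------------------------------

def generate_probe_alignments(
    cfg: SyntheticConfig, truth: PlantedTruth
) -> tuple[pd.DataFrame, ProbeTranscriptMap]:
    """Alignment hit table plus the hand-derived expected surviving map.

    Every real transcript gets one probe set of 5-8 perfect single-target
    probes (all survive).  Decoy transcripts exercise each filtering rule:

    * ``DECOY_FEW`` — only 4 perfect probes, excluded by the >4-probe rule;
    * ``DECOY_IMPERFECT`` — 6 probes of which 3 imperfect, excluded;
    * ``DECOY_AMB_A`` / ``DECOY_AMB_B`` — share one ambiguous probe, which is
      deleted; A keeps 5 probes and survives, B keeps 4 and is excluded;
    * ``DECOY_SPLIT_1`` / ``DECOY_SPLIT_2`` — one probe set whose probes split
      across two transcripts, so the set is unmapped and both are excluded.

    The expected map is written down from this construction, not computed by
    the filtering code.
    """
    cfg.validate()
    rng = _rng(cfg, stream=3)
    rows: list[tuple[str, str, str, str, bool]] = []
    mapping: dict[str, str] = {}
    support: dict[str, int] = {}

    feats = cfg.lncrna_ids() + cfg.mrna_ids()
    for fid in feats:
        bt = LNCRNA if fid.startswith("LNC") else MRNA
        n_probes = int(rng.integers(5, 9))
        ps = f"PS_{fid}"
        for j in range(n_probes):
            rows.append((f"{fid}_p{j}", ps, fid, bt, True))
        mapping[ps] = fid
        support[fid] = n_probes

    # rule edge cases (all mRNA decoys)
    for j in range(4):
        rows.append((f"DECOY_FEW_p{j}", "PS_DECOY_FEW", "DECOY_FEW", MRNA, True))
    for j in range(6):
        rows.append(
            (f"DECOY_IMP_p{j}", "PS_DECOY_IMP", "DECOY_IMPERFECT", MRNA, j < 3)
        )
    for j in range(6):
        rows.append((f"AMB_A_p{j}", "PS_AMB_A", "DECOY_AMB_A", MRNA, True))
    rows.append(("AMB_A_p0", "PS_AMB_A", "DECOY_AMB_B", MRNA, True))  # ambiguous
    for j in range(4):
        rows.append((f"AMB_B_p{j}", "PS_AMB_B", "DECOY_AMB_B", MRNA, True))
    for j in range(5):
        rows.append((f"SPLIT_p{j}", "PS_SPLIT", "DECOY_SPLIT_1", MRNA, True))
    for j in range(5, 10):
        rows.append((f"SPLIT_p{j}", "PS_SPLIT", "DECOY_SPLIT_2", MRNA, True))

    mapping["PS_AMB_A"] = "DECOY_AMB_A"   # survives with 5 probes after deletion
    support["DECOY_AMB_A"] = 5

    hits = pd.DataFrame(
        rows,
        columns=["probe_id", "probe_set_id", "transcript_id", "biotype", "perfect_match"],
    )
    expected = ProbeTranscriptMap(mapping=mapping, support=support)
    return hits, expected


# ---------------------------------------------------------------------------
# clinical cohort and qPCR
# ---------------------------------------------------------------------------

def generate_clinical_table(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic clinical cohort and qPCR Ct table.

    The case group is drawn with higher BMI, LH, testosterone, AMH, fasting
    glucose and insulin, spanning realistic PCOS/control ranges; scaling
    ``clinical_effect`` toward 0 collapses both groups onto the control
    distribution (a null cohort).  Target-gene Ct values are generated so
    that relative hub expression increases with HOMA-IR.
    """
    cfg.validate()
    rng = _rng(cfg, stream=4)
    e = cfg.clinical_effect

    def draw(n: int, ctrl: tuple[float, float], pcos: tuple[float, float],
             is_pcos: bool, lognorm: bool = False) -> np.ndarray:
        mu = ctrl[0] + (pcos[0] - ctrl[0]) * (e if is_pcos else 0.0)
        sd = ctrl[1] + (pcos[1] - ctrl[1]) * (e if is_pcos else 0.0)
        if lognorm:
            sigma = math.sqrt(math.log(1 + (sd / mu) ** 2))
            return rng.lognormal(math.log(mu) - sigma**2 / 2, sigma, n)
        return np.maximum(rng.normal(mu, sd, n), 0.05)

    frames = []
    for group, n, is_pcos in (
        ("PCOS", cfg.n_pcos_subjects, True),
        ("control", cfg.n_control_subjects, False),
    ):
        frames.append(pd.DataFrame({
            "subject_id": [f"{group[:3].upper()}{i:03d}" for i in range(1, n + 1)],
            "group": group,
            "age": draw(n, (28.8, 2.9), (28.2, 3.5), is_pcos),
            "bmi": draw(n, (22.2, 2.9), (25.9, 3.6), is_pcos),
            "fsh": draw(n, (6.30, 1.37), (5.59, 1.00), is_pcos),
            "lh": draw(n, (5.12, 1.92), (9.64, 4.57), is_pcos),
            "testosterone": draw(n, (20.1, 7.0), (42.3, 21.5), is_pcos, lognorm=True),
            "amh": draw(n, (5.09, 3.13), (9.74, 4.15), is_pcos, lognorm=True),
            "fasting_glucose": draw(n, (5.35, 0.35), (5.59, 0.52), is_pcos),
            "fasting_insulin": draw(n, (9.31, 3.53), (20.6, 14.0), is_pcos, lognorm=True),
        }))
    clinical = pd.concat(frames, ignore_index=True)

    homa = clinical["fasting_insulin"] * clinical["fasting_glucose"] / 22.5
    ct_ref = rng.normal(15.0, 0.5, len(clinical))
    delta_ct = 6.0 - 1.0 * np.log2(homa) + rng.normal(0.0, 0.4, len(clinical))
    qpcr = pd.DataFrame({
        "subject_id": clinical["subject_id"],
        "group": clinical["group"],
        "ct_target": np.clip(ct_ref + delta_ct, 1.0, 44.0),
        "ct_reference": np.clip(ct_ref, 1.0, 44.0),
    })
    return clinical, qpcr


# ---------------------------------------------------------------------------
# dedicated co-expression fixtures
# ---------------------------------------------------------------------------

def generate_planted_modules(
    sizes: tuple[int, ...] = (40, 35, 30),
    within_cor: float = 0.8,
    n_samples: int = 13,
    trait_cor: float = 0.95,
    seed: int = 0,
    background_cor: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Expression with planted co-expression modules for module detection.

    Each module m has its own latent factor z_m; member f is
    ``sqrt(rho) * z_m + sqrt(1-rho) * eps`` so the within-module correlation
    is ``rho``.  The factors are mutually orthogonalized (and, beyond the
    first, orthogonal to the trait), so the planted between-module
    correlation is exactly the stated background of zero rather than zero
    plus small-sample noise.  The first module's factor is tied to a binary
    trait at correlation ``trait_cor``.  Returns (matrix, truth labels,
    trait).
    """
    if not 0.0 <= within_cor < 1.0:
        raise ValueError("within_cor must lie in [0, 1)")
    if len(sizes) + 1 > n_samples:
        raise ValueError("need more samples than module factors to orthogonalize")
    rng = np.random.default_rng(seed)
    cols = [f"S{i:02d}" for i in range(n_samples)]
    trait = np.zeros(n_samples)
    trait[: (n_samples + 1) // 2] = 1.0
    trait_std = (trait - trait.mean()) / trait.std()

    def orthogonalized(previous: list[np.ndarray]) -> np.ndarray:
        v = rng.standard_normal(n_samples)
        v -= v.mean()
        for b in previous:
            v -= (v @ b) / (b @ b) * b
        return v / v.std()

    basis = [trait_std]
    factors = []
    for m, _ in enumerate(sizes, start=1):
        u = orthogonalized(basis)
        basis.append(u)
        if m == 1:
            factors.append(trait_cor * trait_std + math.sqrt(1 - trait_cor**2) * u)
        else:
            factors.append(u)

    rows, labels, feats = [], [], []
    for m, size in enumerate(sizes, start=1):
        z = factors[m - 1]
        for j in range(size):
            eps = rng.standard_normal(n_samples)
            rows.append(math.sqrt(within_cor) * z + math.sqrt(1 - within_cor) * eps)
            feats.append(f"M{m}F{j:03d}")
            labels.append(f"M{m}")
    del background_cor  # background features are omitted (cor 0 by absence)
    mat = pd.DataFrame(np.array(rows), index=feats, columns=cols)
    return mat, pd.Series(labels, index=feats, name="module"), pd.Series(
        trait, index=cols, name="trait"
    )


def generate_scale_free_expression(
    n_features: int = 300, n_samples: int = 80, seed: int = 0,
    pareto_shape: float = 2.0, loading_scale: float = 0.6,
) -> pd.DataFrame:
    """Single-factor expression with heavy-tailed loadings.

    Connectivity of the soft-thresholded correlation network then follows an
    approximate power law (a few strongly-loaded hub features, many weak
    ones), the regime in which the scale-free fit index is informative.
    """
    rng = np.random.default_rng(seed)
    w = loading_scale * rng.pareto(pareto_shape, n_features)
    z = rng.standard_normal(n_samples)
    mat = w[:, None] * z[None, :] + rng.standard_normal((n_features, n_samples))
    return pd.DataFrame(
        mat,
        index=[f"G{i:04d}" for i in range(n_features)],
        columns=[f"S{i:02d}" for i in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# fixture writer (TSV outputs + truth sidecar)
# ---------------------------------------------------------------------------

def write_fixture(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write all fixture tables as TSV plus the truth sidecar JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lnc_tab, mrna_tab, truth = generate_interaction_tables(cfg)
    bundle = generate_expression_dataset(cfg, truth)
    hits, expected = generate_probe_alignments(cfg, truth)
    clinical, qpcr = generate_clinical_table(cfg)

    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index, float_format="%.10g")
        paths[name] = p

    save("lncrna_rbp", lnc_tab)
    save("mrna_rbp", mrna_tab)
    save("expression_case_control", bundle.case_control.matrix, index=True)
    save("expression_paired", bundle.paired.matrix, index=True)
    labels_cc = bundle.case_control.labels.rename("label").rename_axis("sample")
    save("labels_case_control", labels_cc.reset_index())
    lab_p = pd.DataFrame({
        "sample": bundle.paired.samples,
        "label": bundle.paired.labels.values,
        "subject": bundle.paired.pairing.values,
    })
    save("labels_paired", lab_p)
    bio = bundle.case_control.biotype.rename_axis("feature").reset_index()
    save("biotype", bio)
    save("probe_alignments", hits)
    save("clinical", clinical)
    save("qpcr", qpcr)
    expected_df = pd.DataFrame(
        [(ps, t, expected.support[t]) for ps, t in sorted(expected.mapping.items())],
        columns=["probe_set_id", "transcript_id", "support"],
    )
    save("expected_probe_map", expected_df)

    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(asdict(cfg), indent=2, sort_keys=True, default=list))
    paths["config"] = cfg_path
    return paths
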