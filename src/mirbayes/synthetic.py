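"""Synthetic qRT-PCR cohorts with the statistical structure the analysis assumes.

Generative model, per sample:

1. a latent class (target/versus) according to the configured class sizes;
2. latent normalized deltas ``(dx_a, dx_b)`` drawn from the class's bivariate
   normal (means, SDs and within-class correlation configured per class);
3. a latent reference level ``x_ref`` from the class's reference Gaussian;
   raw marker levels are ``x_a = dx_a + x_ref`` and ``x_b = dx_b + x_ref``
   (the markers share the reference's sample-to-sample variation, one
   consistent choice of the raw joint law — only the normalized law is
   pinned down by the study conditions);
4. an additive session offset per assay (all assays of a session shift
   together, which is exactly what reference normalization cancels);
5. three technical replicates per assay: latent value plus iid normal noise
   of SD ``sigma_rep * sqrt(2)``. With the n-1 sample variance of a
   triplicate, this makes ``s^2 / sigma_rep^2 ~ chi-square(nu=2)`` — the
   variance law the QC stage fits — so the fitted scale recovers
   ``sigma_rep`` directly. The sqrt(2) factor is deliberate and documented:
   sigma_rep is the *law's* scale, not the per-replicate noise SD.
6. injected faults: a *variability outlier* multiplies one triplicate's
   replicate noise by a configurable inflation factor; a *bias outlier*
   shifts all three replicates of the discriminating marker jointly by a
   configurable amount with random sign.

Randomness is one seeded stream split per sample (in sample order), so a
(config, seed) pair yields a bit-identical cohort regardless of how the
loop is executed.

The *default* configuration is the reference lung-carcinoma study
condition encoded throughout this package's documentation: class Gaussians
and within-class correlations of the normalized measures, replicate-noise
scales per assay, two sessions with few-Ct additive offsets, and class
sizes 18/15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .data_io import Cohort, TriplicateRecord
from .errors import ConfigurationError


def _default_delta_a() -> dict:
    return {"target": (1.7, 2.2), "versus": (-4.6, 2.4)}


def _default_delta_b() -> dict:
    return {"target": (-6.5, 1.4), "versus": (-6.6, 2.4)}


def _default_reference() -> dict:
    return {"target": (25.0, 1.4), "versus": (25.8, 1.9)}


def _default_corr() -> dict:
    return {"target": 0.49, "versus": 0.75}


def _default_sigma_rep() -> dict:
    return {"miR-205": 0.25, "miR-21": 0.19, "U6": 0.19}


def _default_offsets() -> dict:
    # session II runs a few Ct higher than session I on every assay; the
    # per-assay values follow the observed audit pattern (~3 Ct for the
    # markers, ~2.4 Ct for the reference)
    return {
        "I": {"miR-205": 0.0, "miR-21": 0.0, "U6": 0.0},
        "II": {"miR-205": 2.7, "miR-21": 3.0, "U6": 2.4},
    }


@dataclass
class SyntheticConfig:
    """Full generative description of a cohort.

    Per-class entries are ``(mean, sd)`` pairs in Ct units. ``delta_a`` /
    ``delta_b`` are the normalized measures of the discriminating and the
    helper marker; ``delta_corr`` is their within-class correlation.
    ``sigma_rep`` is the replicate-variance scale per assay (the chi-square
    law's sigma, see module docstring). Outlier rates are per triplicate
    (variability) and per sample (bias).
    """

    n_target: int = 18
    n_versus: int = 15
    marker_a: str = "miR-205"
    marker_b: str = "miR-21"
    reference: str = "U6"
    delta_a: dict = field(default_factory=_default_delta_a)
    delta_b: dict = field(default_factory=_default_delta_b)
    reference_stats: dict = field(default_factory=_default_reference)
    delta_corr: dict = field(default_factory=_default_corr)
    sigma_rep: dict = field(default_factory=_default_sigma_rep)
    session_offsets: dict = field(default_factory=_default_offsets)
    variability_outlier_rate: float = 0.0
    variability_inflation: float = 5.0
    bias_outlier_rate: float = 0.0
    bias_shift: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_target < 1 or self.n_versus < 1:
            raise ConfigurationError("class sizes must be >= 1")
        for name, table in (("delta_a", self.delta_a), ("delta_b", self.delta_b),
                            ("reference_stats", self.reference_stats)):
            for cls in ("target", "versus"):
                mu, sd = table[cls]
                if not sd > 0:
                    raise ConfigurationError(f"{name}[{cls}] SD must be > 0, got {sd}")
        for cls, r in self.delta_corr.items():
            if not -1.0 < r < 1.0:
                raise ConfigurationError(f"delta_corr[{cls}] must lie in (-1, 1), got {r}")
        for assay, s in self.sigma_rep.items():
            if s < 0:
                raise ConfigurationError(f"sigma_rep[{assay}] must be >= 0, got {s}")
        for rate in (self.variability_outlier_rate, self.bias_outlier_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"outlier rates must lie in [0, 1], got {rate}")
        assays = {self.marker_a, self.marker_b, self.reference}
        if len(assays) != 3:
            raise ConfigurationError("marker_a, marker_b and reference must be distinct")
        missing = assays - set(self.sigma_rep)
        if missing:
            raise ConfigurationError(f"sigma_rep missing assays {sorted(missing)}")

    # -- plain-text config round-trip -------------------------------------
    def to_dict(self) -> dict:
        doc = asdict(self)
        for key in ("delta_a", "delta_b", "reference_stats"):
            doc[key] = {cls: list(v) for cls, v in doc[key].items()}
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticConfig":
        doc = dict(doc)
        for key in ("delta_a", "delta_b", "reference_stats"):
            if key in doc:
                doc[key] = {c: tuple(v) for c, v in doc[key].items()}
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def study_config() -> SyntheticConfig:
    """The reference study condition — identical to the defaults."""
    return SyntheticConfig()


@dataclass
class GroundTruth:
    """Injected-fault bookkeeping for calibration tests."""

    variability_outliers: set = field(default_factory=set)  # (sample_id, assay)
    bias_outliers: set = field(default_factory=set)  # sample_id
    latent: dict = field(default_factory=dict)  # sample_id -> {measure: value}


def _triplicate(rng: np.random.Generator, latent: float, noise_sd: float) -> tuple[float, ...]:
    return tuple(float(v) for v in latent + rng.normal(0.0, noise_sd, 3))


def generate_cohort(
    config: SyntheticConfig,
    seed: int | None = None,
    return_truth: bool = False,
):
    """Generate a cohort under the configured law.

    ``seed`` overrides ``config.seed``. With ``return_truth=True`` also
    returns the :class:`GroundTruth` of injected faults and latent values.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    n = config.n_target + config.n_versus
    children = root.spawn(n)
    sessions = sorted(config.session_offsets)

    records: list[TriplicateRecord] = []
    truth = GroundTruth()
    width = max(3, len(str(n)))
    for i in range(n):
        rng = np.random.default_rng(children[i])
        cls = "target" if i < config.n_target else "versus"
        sample_id = f"S{i + 1:0{width}d}"
        session = sessions[i % len(sessions)] if sessions else None

        mu_a, sd_a = config.delta_a[cls]
        mu_b, sd_b = config.delta_b[cls]
        r = config.delta_corr[cls]
        cov = [
            [sd_a**2, r * sd_a * sd_b],
            [r * sd_a * sd_b, sd_b**2],
        ]
        d_a, d_b = rng.multivariate_normal([mu_a, mu_b], cov)
        mu_ref, sd_ref = config.reference_stats[cls]
        x_ref = rng.normal(mu_ref, sd_ref)
        latent = {
            config.marker_a: d_a + x_ref,
            config.marker_b: d_b + x_ref,
            config.reference: x_ref,
        }
        truth.latent[sample_id] = {
            "dx_a": d_a,
            "dx_b": d_b,
            "x_ref": x_ref,
        }

        bias = rng.random() < config.bias_outlier_rate
        if bias:
            truth.bias_outliers.add(sample_id)
            latent[config.marker_a] += config.bias_shift * (1 if rng.random() < 0.5 else -1)

        offsets = config.session_offsets.get(session, {}) if session else {}
        for assay in (config.marker_a, config.marker_b, config.reference):
            noise_sd = config.sigma_rep[assay] * math.sqrt(2.0)
            if rng.random() < config.variability_outlier_rate:
                truth.variability_outliers.add((sample_id, assay))
                noise_sd *= config.variability_inflation
            value = latent[assay] + offsets.get(assay, 0.0)
            records.append(
                TriplicateRecord(
                    sample_id=sample_id,
                    assay=assay,
                    replicates=_triplicate(rng, value, noise_sd),
                    session=session,
                    class_label=cls,
                )
            )

    cohort = Cohort(
        records=records,
        assays=[config.marker_a, config.marker_b, config.reference],
    )
    return (cohort, truth) if return_truth else cohort


# ---------------------------------------------------------------------------
# deterministic moment-matched stand-in cohort
# ---------------------------------------------------------------------------

def _standardize(z: np.ndarray) -> np.ndarray:
    return (z - z.mean()) / z.std(ddof=1)


def _moment_matched_pair(
    rng: np.random.Generator, n: int, stats_a: tuple, stats_b: tuple, r: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n pairs whose *sample* means, SDs and correlation are exact."""
    z1 = _standardize(rng.standard_normal(n))
    z2 = rng.standard_normal(n)
    z2 = z2 - z1 * (np.sum(z1 * z2) / np.sum(z1 * z1))  # exact orthogonality
    z2 = _standardize(z2)
    e2 = r * z1 + math.sqrt(1.0 - r * r) * z2
    e2 = _standardize(e2)  # renormalize (z1, z2 exactly uncorrelated, so corr stays r)
    mu_a, sd_a = stats_a
    mu_b, sd_b = stats_b
    return mu_a + sd_a * z1, mu_b + sd_b * e2


_PATTERNS = (
    (-1.0, 0.0, 1.0),
    (1.0, 0.0, -1.0),
    (0.0, 1.0, -1.0),
    (0.0, -1.0, 1.0),
    (1.0, -1.0, 0.0),
    (-1.0, 1.0, 0.0),
)  # each has mean 0 and n-1 sample SD 1


def _exact_triplicate(x: float, s: float, k: int) -> tuple[float, ...]:
    """Three replicates with sample mean exactly x and sample SD exactly s."""
    u = _PATTERNS[k % len(_PATTERNS)]
    return tuple(x + s * ui for ui in u)


def _stratified_sds(sigma: float, m: int, top: float = 0.90) -> np.ndarray:
    """m clean triplicate SDs at stratified quantiles of the chi-square(2)
    variance law, compressed to the (0, top] probability range so that none
    of them crosses the alpha = 0.05 outlier threshold."""
    p = top * (np.arange(1, m + 1) - 0.5) / m
    return sigma * np.sqrt(-2.0 * np.log1p(-p))


def study_like_cohort(seed: int = 73) -> Cohort:
    """Deterministic *synthetic* stand-in for the reference study cohort.

    This is not measured data: it is a reconstruction that reproduces the
    study conditions' published summary structure exactly where the
    analysis depends on it — per-class sample means/SDs of the normalized
    measures and of the reference (to the digit), within-class correlations
    of the two normalized markers, per-assay replicate-SD populations
    following the chi-square(2) law at the study scales, set sizes
    (39 samples; the discriminating marker measured on 37), and exactly 4
    reference triplicates with inflated variability. Replicate SDs of the
    clean triplicates sit at stratified quantiles of the variance law, so
    the QC fit recovers the configured scales and flags exactly the
    injected outliers.

    Layout: 21 target + 18 versus samples; 2 + 2 carry the inflated
    reference triplicates; one further sample per class lacks the
    discriminating marker. The fully-measured subset is 18 target + 15
    versus samples.
    """
    cfg = study_config()
    rng = np.random.default_rng(seed)

    n_t, n_v = 21, 18
    t_ids = [f"T{i + 1:02d}" for i in range(n_t)]
    v_ids = [f"V{i + 1:02d}" for i in range(n_v)]

    # per class: fully-measured pair subset / extra valid sample / U6 outliers
    plan = {
        "target": {"ids": t_ids, "pairs": t_ids[:18], "no_marker_a": t_ids[18], "ref_out": t_ids[19:]},
        "versus": {"ids": v_ids, "pairs": v_ids[:15], "no_marker_a": v_ids[15], "ref_out": v_ids[16:]},
    }

    d_a: dict[str, float] = {}
    d_b: dict[str, float] = {}
    x_ref: dict[str, float] = {}
    for cls, lay in plan.items():
        pairs = lay["pairs"]
        da, db = _moment_matched_pair(
            rng, len(pairs), cfg.delta_a[cls], cfg.delta_b[cls], cfg.delta_corr[cls]
        )
        for sid, a, b in zip(pairs, da, db):
            d_a[sid], d_b[sid] = float(a), float(b)
        # extra valid sample and reference outliers: class-mean latents
        for sid in [lay["no_marker_a"], *lay["ref_out"]]:
            d_a[sid] = cfg.delta_a[cls][0]
            d_b[sid] = cfg.delta_b[cls][0]
        valid = [s for s in lay["ids"] if s not in lay["ref_out"]]
        mu_r, sd_r = cfg.reference_stats[cls]
        zr = _standardize(rng.standard_normal(len(valid)))
        for sid, z in zip(valid, zr):
            x_ref[sid] = mu_r + sd_r * float(z)
        for sid in lay["ref_out"]:
            x_ref[sid] = mu_r

    all_ids = t_ids + v_ids
    cls_of = {sid: ("target" if sid.startswith("T") else "versus") for sid in all_ids}
    measured_a = [s for s in all_ids if s not in (plan["target"]["no_marker_a"], plan["versus"]["no_marker_a"])]
    ref_outliers = set(plan["target"]["ref_out"]) | set(plan["versus"]["ref_out"])

    # replicate SDs: stratified clean quantiles per assay; inflated reference SDs
    sds: dict[tuple[str, str], float] = {}
    sigma_ref = cfg.sigma_rep[cfg.reference]
    clean_ref = [s for s in all_ids if s not in ref_outliers]
    for sid, s in zip(clean_ref, _stratified_sds(sigma_ref, len(clean_ref))):
        sds[(sid, cfg.reference)] = float(s)
    for sid in sorted(ref_outliers):
        sds[(sid, cfg.reference)] = 1.5 * math.sqrt(-2.0 * math.log(0.05)) * sigma_ref
    for assay, members in ((cfg.marker_a, measured_a), (cfg.marker_b, all_ids)):
        for sid, s in zip(members, _stratified_sds(cfg.sigma_rep[assay], len(members))):
            sds[(sid, assay)] = float(s)

    records: list[TriplicateRecord] = []
    for k, sid in enumerate(all_ids):
        cls = cls_of[sid]
        session = "I" if k % 2 == 0 else "II"
        latents = {
            cfg.marker_b: d_b[sid] + x_ref[sid],
            cfg.reference: x_ref[sid],
        }
        if sid in measured_a:
            latents[cfg.marker_a] = d_a[sid] + x_ref[sid]
        for assay in (cfg.marker_a, cfg.marker_b, cfg.reference):
            if assay not in latents:
                continue
            records.append(
                TriplicateRecord(
                    sample_id=sid,
                    assay=assay,
                    replicates=_exact_triplicate(latents[assay], sds[(sid, assay)], k),
                    session=session,
                    class_label=cls,
                )
            )
    return Cohort(records=records, assays=[cfg.marker_a, cfg.marker_b, cfg.reference])
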