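"""Seeded synthetic multimodal oncology cohorts.

Each patient carries three modalities — a small single-channel image, an
integer genomic token sequence, and a numeric clinical vector — plus a class
label, a domain identifier (source/target acquisition site) and a
modality-presence mask.  Every modality renders the same per-class latent
prototype, so per-modality informativeness is directly controllable:

* image: the prototype is projected onto a low-spatial-frequency cosine basis
  to give a smooth intensity pattern, plus Gaussian pixel noise;
* genomic: tokens are drawn from a class-conditional categorical whose logits
  are a fixed linear projection of the prototype (plus logit noise);
* clinical: a fixed affine map of the prototype plus Gaussian noise.

Setting an informativeness weight to 0 makes that modality pure noise.
Domain shift (an affine intensity/feature perturbation emulating acquisition
differences) applies to image intensities and clinical features only — token
identities are left untouched, mimicking platform shift rather than biology.

Identical configs (including the seed) produce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MODALITIES = ("image", "genomic", "clinical")

_LATENT_DIM = 16  # dimensionality of the per-class prototype


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


class CohortFormatError(ValueError):
    """Raised when on-disk cohort files are malformed or inconsistent."""


@dataclass(frozen=True)
class DomainShiftParams:
    """Affine acquisition shift applied to the target-domain patients."""

    target_fraction: float = 0.0
    mean_shift: float = 0.0
    scale_shift: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ConfigError(
                f"target_fraction must be in [0, 1], got {self.target_fraction}"
            )
        if self.scale_shift <= 0.0:
            raise ConfigError(f"scale_shift must be > 0, got {self.scale_shift}")


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 200
    image_shape: tuple = (8, 8, 1)
    genomic_length: int = 16
    vocab_size: int = 12
    clinical_dim: int = 8
    n_classes: int = 2
    informativeness: tuple = (0.6, 0.6, 0.6)  # (image, genomic, clinical)
    noise_sd: float = 0.5
    shift: DomainShiftParams = field(default_factory=DomainShiftParams)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if len(self.image_shape) != 3 or any(s < 1 for s in self.image_shape):
            raise ConfigError(f"image_shape must be (H, W, C) >= 1, got {self.image_shape}")
        if self.genomic_length < 1:
            raise ConfigError(f"genomic_length must be >= 1, got {self.genomic_length}")
        if self.vocab_size < 2:
            raise ConfigError(f"vocab_size must be >= 2, got {self.vocab_size}")
        if self.clinical_dim < 1:
            raise ConfigError(f"clinical_dim must be >= 1, got {self.clinical_dim}")
        if len(self.informativeness) != 3 or any(
            not 0.0 <= w <= 1.0 for w in self.informativeness
        ):
            raise ConfigError(
                f"informativeness must be 3 weights in [0, 1], got {self.informativeness}"
            )
        if self.noise_sd < 0.0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        self.shift.validate()


@dataclass
class PatientSample:
    patient_id: str
    image: np.ndarray       # (H, W, C) float64
    genomic: np.ndarray     # (m,) int64 tokens
    clinical: np.ndarray    # (p,) float64
    label: int
    domain_id: str          # "source" or "target"
    modality_mask: np.ndarray  # (3,) bool, order (image, genomic, clinical)

    def __eq__(self, other):
        if not isinstance(other, PatientSample):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and np.array_equal(self.image, other.image)
            and np.array_equal(self.genomic, other.genomic)
            and np.array_equal(self.clinical, other.clinical)
            and self.label == other.label
            and self.domain_id == other.domain_id
            and np.array_equal(self.modality_mask, other.modality_mask)
        )


def _cosine_image_basis(h: int, w: int, c: int, latent_dim: int) -> np.ndarray:
    """Low-frequency separable cosine patterns, one (H, W, C) image per latent."""
    n_freq = int(np.ceil(np.sqrt(latent_dim)))
    ys = (np.arange(h) + 0.5) / h
    xs = (np.arange(w) + 0.5) / w
    basis = []
    for k in range(latent_dim):
        fy, fx = divmod(k, n_freq)
        pattern = np.cos(np.pi * fy * ys)[:, None] * np.cos(np.pi * fx * xs)[None, :]
        basis.append(np.repeat(pattern[:, :, None], c, axis=2))
    b = np.stack(basis)  # (latent_dim, H, W, C)
    return b / np.sqrt(latent_dim)


def generate_cohort(config: CohortConfig) -> list[PatientSample]:
    """Draw a full synthetic cohort; bit-identical under identical config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w, c = config.image_shape
    m, p, k = config.genomic_length, config.clinical_dim, config.n_classes
    inf_img, inf_gen, inf_clin = config.informativeness

    prototypes = rng.normal(size=(k, _LATENT_DIM))
    image_basis = _cosine_image_basis(h, w, c, _LATENT_DIM)
    genomic_proj = rng.normal(size=(_LATENT_DIM, config.vocab_size)) / np.sqrt(_LATENT_DIM)
    clinical_proj = rng.normal(size=(_LATENT_DIM, p)) / np.sqrt(_LATENT_DIM)
    clinical_offset = rng.normal(size=p)

    labels = rng.integers(0, k, size=config.n_patients)

    # deterministic domain assignment: first floor(fraction * n) of a seeded shuffle
    order = rng.permutation(config.n_patients)
    n_target = int(np.floor(config.shift.target_fraction * config.n_patients))
    target_ids = set(order[:n_target].tolist())

    samples: list[PatientSample] = []
    for i in range(config.n_patients):
        u = prototypes[labels[i]]
        image = inf_img * np.tensordot(u, image_basis, axes=1)
        image = image + rng.normal(0.0, config.noise_sd, size=(h, w, c))

        logits = inf_gen * (u @ genomic_proj)
        logits = logits + rng.normal(0.0, config.noise_sd, size=config.vocab_size)
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        genomic = rng.choice(config.vocab_size, size=m, p=probs).astype(np.int64)

        clinical = inf_clin * (u @ clinical_proj + clinical_offset)
        clinical = clinical + rng.normal(0.0, config.noise_sd, size=p)

        domain = "target" if i in target_ids else "source"
        if domain == "target":
            # acquisition shift on image intensities and clinical features only
            image = config.shift.scale_shift * image + config.shift.mean_shift
            clinical = config.shift.scale_shift * clinical + config.shift.mean_shift

        samples.append(
            PatientSample(
                patient_id=f"P{i:05d}",
                image=image,
                genomic=genomic,
                clinical=clinical,
                label=int(labels[i]),
                domain_id=domain,
                modality_mask=np.ones(3, dtype=bool),
            )
        )

    if config.missing_rate > 0.0:
        samples = apply_missingness(samples, config.missing_rate, seed=config.seed + 1)
    return samples


def apply_missingness(samples, missing_rate: float, seed: int) -> list[PatientSample]:
    """Independently drop each modality flag with probability ``missing_rate``.

    If all three modalities of a patient would be dropped, one uniformly
    chosen modality is restored — the architecture needs at least one input
    stream.  Absent modalities have their content zero-filled (a sentinel;
    downstream code must consult the mask, never the content).
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ConfigError(f"missing_rate must be in [0, 1], got {missing_rate}")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        absent = rng.random(3) < missing_rate
        if absent.all():
            absent[rng.integers(0, 3)] = False
        mask = s.modality_mask & ~absent
        out.append(
            PatientSample(
                patient_id=s.patient_id,
                image=s.image if mask[0] else np.zeros_like(s.image),
                genomic=s.genomic if mask[1] else np.zeros_like(s.genomic),
                clinical=s.clinical if mask[2] else np.zeros_like(s.clinical),
                label=s.label,
                domain_id=s.domain_id,
                modality_mask=mask,
            )
        )
    return out


# -- serialization ----------------------------------------------------------
#
# Layout of a cohort directory:
#   manifest.tsv   patient_id, label, domain_id, mask_image, mask_genomic, mask_clinical
#   clinical.tsv   patient_id + one named column per clinical feature (c0..c{p-1})
#   genomic.tsv    patient_id, tokens (space-separated integers)
#   images.npz     one array per patient, keyed by patient_id
#
# Text files are UTF-8, tab-delimited, with a header row; floats are written
# with 17 significant digits so a round trip is exact.

def write_cohort(samples, path) -> None:
    os.makedirs(path, exist_ok=True)
    manifest = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in samples],
            "label": [s.label for s in samples],
            "domain_id": [s.domain_id for s in samples],
            "mask_image": [int(s.modality_mask[0]) for s in samples],
            "mask_genomic": [int(s.modality_mask[1]) for s in samples],
            "mask_clinical": [int(s.modality_mask[2]) for s in samples],
        }
    )
    manifest.to_csv(os.path.join(path, "manifest.tsv"), sep="\t", index=False)

    p = samples[0].clinical.shape[0] if samples else 0
    clinical = pd.DataFrame(
        [s.clinical for s in samples], columns=[f"c{j}" for j in range(p)]
    )
    clinical.insert(0, "patient_id", [s.patient_id for s in samples])
    clinical.to_csv(
        os.path.join(path, "clinical.tsv"), sep="\t", index=False, float_format="%.17g"
    )

    genomic = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in samples],
            "tokens": [" ".join(str(t) for t in s.genomic) for s in samples],
        }
    )
    genomic.to_csv(os.path.join(path, "genomic.tsv"), sep="\t", index=False)

    np.savez(
        os.path.join(path, "images.npz"),
        **{s.patient_id: s.image for s in samples},
    )


def read_cohort(path) -> list[PatientSample]:
    manifest_path = os.path.join(path, "manifest.tsv")
    try:
        manifest = pd.read_csv(manifest_path, sep="\t", dtype={"patient_id": str})
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise CohortFormatError(f"cannot read manifest at {manifest_path}: {exc}") from exc
    required = {"patient_id", "label", "domain_id",
                "mask_image", "mask_genomic", "mask_clinical"}
    if not required.issubset(manifest.columns):
        raise CohortFormatError(
            f"manifest missing columns {sorted(required - set(manifest.columns))}"
        )
    if manifest.empty:
        return []

    clinical = pd.read_csv(os.path.join(path, "clinical.tsv"), sep="\t",
                           dtype={"patient_id": str},
                           float_precision="round_trip").set_index("patient_id")
    genomic = pd.read_csv(os.path.join(path, "genomic.tsv"), sep="\t",
                          dtype={"patient_id": str, "tokens": str}).set_index("patient_id")
    with np.load(os.path.join(path, "images.npz")) as images:
        samples = []
        for row in manifest.itertuples(index=False):
            pid = row.patient_id
            if pid not in images:
                raise CohortFormatError(f"manifest references missing image for {pid}")
            if pid not in clinical.index:
                raise CohortFormatError(f"manifest references missing clinical row for {pid}")
            if pid not in genomic.index:
                raise CohortFormatError(f"manifest references missing genomic row for {pid}")
            tokens_field = genomic.loc[pid, "tokens"]
            tokens = (
                np.array([], dtype=np.int64)
                if pd.isna(tokens_field) or tokens_field == ""
                else np.array(tokens_field.split(" "), dtype=np.int64)
            )
            samples.append(
                PatientSample(
                    patient_id=pid,
                    image=np.asarray(images[pid], dtype=np.float64),
                    genomic=tokens,
                    clinical=clinical.loc[pid].to_numpy(dtype=np.float64),
                    label=int(row.label),
                    domain_id=str(row.domain_id),
                    modality_mask=np.array(
                        [row.mask_image, row.mask_genomic, row.mask_clinical], dtype=bool
                    ),
                )
            )
    return samples


def cohort_arrays(samples) -> dict:
    """Stack a cohort into batched arrays (the layout the models consume)."""
    return {
        "image": np.stack([s.image for s in samples]),
        "genomic": np.stack([s.genomic for s in samples]),
        "clinical": np.stack([s.clinical for s in samples]),
        "label": np.array([s.label for s in samples], dtype=np.int64),
        "mask": np.stack([s.modality_mask for s in samples]),
        "domain": np.array([s.domain_id for s in samples]),
        "patient_id": [s.patient_id for s in samples],
    }


def replace_config(config: CohortConfig, **kwargs) -> CohortConfig:
    """Return a copy of ``config`` with fields replaced (convenience)."""
    return replace(config, **kwargs)


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["image_shape"] = list(config.image_shape)
    d["informativeness"] = list(config.informativeness)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "shift" in d and isinstance(d["shift"], dict):
        d["shift"] = DomainShiftParams(**d["shift"])
    if "image_shape" in d:
        d["image_shape"] = tuple(d["image_shape"])
    if "informativeness" in d:
        d["informativeness"] = tuple(d["informativeness"])
    return CohortConfig(**d)
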