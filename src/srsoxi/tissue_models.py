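"""Layered tissue models and optical-property presets.

A :class:`TissueModel` is an ordered stack of slabs, top first, each slab
carrying per-wavelength optical properties (scattering coefficient ``mu_s``,
absorption coefficient ``mu_a``, anisotropy ``g``, refractive index ``n``).
Photons crossing the bottom of the last layer escape (they are tallied as
transmitted and never re-entered), which models thin organs backed by a
non-scattering space as well as "semi-infinite" media when the stack is made
deep enough that bottom escape is negligible.

Three presets are provided:

``homogeneous_skin``
    A single 40 mm slab with skin scattering and the mean absorption
    coefficient of the four tissue types below — the standard semi-infinite
    medium used for probing-depth analysis.
``skin_subcutaneous``
    Skin (1.5 mm) / subcutaneous fat (2.5 mm) / muscle (20 mm).
``gastric``
    A single 7.0 mm slab of gastric tissue with bottom escape.

Scattering differs slightly between the two LED wavelengths (770 and 830 nm);
absorption and anisotropy are taken equal at both.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ModelValidationError, UnknownPresetError

WAVELENGTHS = (770, 830)

#: Default tissue refractive index (standard MCML convention) and ambient index.
DEFAULT_TISSUE_N = 1.4
DEFAULT_AMBIENT_N = 1.0


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one layer at one wavelength.

    Parameters
    ----------
    mu_s : float
        Scattering coefficient, mm^-1.
    mu_a : float
        Absorption coefficient, mm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection angle), dimensionless, in [0, 1).
    n : float
        Refractive index, >= 1.
    """

    mu_s: float
    mu_a: float
    g: float
    n: float = DEFAULT_TISSUE_N

    def __post_init__(self):
        if self.mu_s < 0:
            raise ModelValidationError(f"mu_s must be >= 0, got {self.mu_s}")
        if self.mu_a < 0:
            raise ModelValidationError(f"mu_a must be >= 0, got {self.mu_a}")
        if not 0.0 <= self.g < 1.0:
            raise ModelValidationError(f"g must be in [0, 1), got {self.g}")
        if self.n < 1.0:
            raise ModelValidationError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), mm^-1."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_s + mu_a, mm^-1."""
        return self.mu_s + self.mu_a


@dataclass(frozen=True)
class Layer:
    """One slab: a thickness and its per-wavelength optical properties."""

    thickness: float
    props_by_wavelength: dict[int, OpticalProperties]

    def __post_init__(self):
        if not self.thickness > 0:
            raise ModelValidationError(
                f"layer thickness must be > 0, got {self.thickness}"
            )

    def props(self, wavelength: int) -> OpticalProperties:
        try:
            return self.props_by_wavelength[int(wavelength)]
        except KeyError:
            raise UnknownPresetError(
                f"layer has no properties for wavelength {wavelength} nm"
            ) from None


@dataclass(frozen=True)
class TissueModel:
    """Ordered slab stack, top first, with bottom escape.

    ``wavelength`` selects which entry of each layer's property mapping the
    transport engine uses; ``ambient_n_top``/``ambient_n_bottom`` are the
    refractive indices of the half-spaces above and below the stack
    (set both equal to the tissue index for matched-boundary studies).
    """

    layers: tuple[Layer, ...]
    wavelength: int = 770
    label: str = ""
    ambient_n_top: float = DEFAULT_AMBIENT_N
    ambient_n_bottom: float = DEFAULT_AMBIENT_N
    bottom_boundary: str = "escape"

    def __post_init__(self):
        if len(self.layers) < 1:
            raise ModelValidationError("a model needs at least one layer")
        if self.bottom_boundary != "escape":
            raise ModelValidationError(
                f"unsupported bottom boundary {self.bottom_boundary!r}"
            )
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def interface_depths(self) -> tuple[float, ...]:
        """Cumulative layer boundary depths, starting at 0 (mm)."""
        depths = [0.0]
        for layer in self.layers:
            depths.append(depths[-1] + layer.thickness)
        return tuple(depths)

    @property
    def total_thickness(self) -> float:
        return self.interface_depths[-1]

    def props(self, index: int, wavelength: int | None = None) -> OpticalProperties:
        return self.layers[index].props(wavelength or self.wavelength)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "wavelength": self.wavelength,
            "ambient_n_top": self.ambient_n_top,
            "ambient_n_bottom": self.ambient_n_bottom,
            "bottom_boundary": self.bottom_boundary,
            "layers": [
                {
                    "thickness_mm": layer.thickness,
                    "properties": {
                        str(wl): {
                            "mu_s_per_mm": p.mu_s,
                            "mu_a_per_mm": p.mu_a,
                            "g": p.g,
                            "n": p.n,
                        }
                        for wl, p in sorted(layer.props_by_wavelength.items())
                    },
                }
                for layer in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TissueModel":
        try:
            layers = tuple(
                Layer(
                    thickness=float(entry["thickness_mm"]),
                    props_by_wavelength={
                        int(wl): OpticalProperties(
                            mu_s=float(p["mu_s_per_mm"]),
                            mu_a=float(p["mu_a_per_mm"]),
                            g=float(p["g"]),
                            n=float(p.get("n", DEFAULT_TISSUE_N)),
                        )
                        for wl, p in entry["properties"].items()
                    },
                )
                for entry in data["layers"]
            )
        except KeyError as exc:
            raise ModelValidationError(f"missing model field: {exc}") from None
        return cls(
            layers=layers,
            wavelength=int(data.get("wavelength", 770)),
            label=str(data.get("label", "")),
            ambient_n_top=float(data.get("ambient_n_top", DEFAULT_AMBIENT_N)),
            ambient_n_bottom=float(data.get("ambient_n_bottom", DEFAULT_AMBIENT_N)),
            bottom_boundary=str(data.get("bottom_boundary", "escape")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TissueModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON serialization (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def replace(self, **kwargs) -> "TissueModel":
        return dataclasses.replace(self, **kwargs)


# -- presets ---------------------------------------------------------------

# Per-tissue values; scattering given as (770 nm, 830 nm), absorption and
# anisotropy shared between wavelengths.
_TISSUE_ROWS = {
    "skin": {"thickness": 1.5, "mu_s": (26.0, 23.0), "mu_a": 0.020, "g": 0.95},
    "fat": {"thickness": 2.5, "mu_s": (24.0, 22.0), "mu_a": 0.003, "g": 0.95},
    "muscle": {"thickness": 20.0, "mu_s": (14.0, 13.0), "mu_a": 0.025, "g": 0.95},
    "gastric": {"thickness": 7.0, "mu_s": (15.0, 14.0), "mu_a": 0.030, "g": 0.92},
}

#: Mean absorption coefficient over the four tissue types (mm^-1), used by the
#: homogeneous skin-like medium.
MEAN_TISSUE_MU_A = sum(row["mu_a"] for row in _TISSUE_ROWS.values()) / len(_TISSUE_ROWS)

#: Depth of the homogeneous slab (mm): deep enough that bottom escape is
#: negligible for source-detector separations up to 30 mm.
HOMOGENEOUS_DEPTH = 40.0

PRESET_NAMES = ("homogeneous_skin", "skin_subcutaneous", "gastric")


def _tissue_layer(name: str, thickness: float | None = None,
                  mu_a: float | None = None, n: float = DEFAULT_TISSUE_N) -> Layer:
    row = _TISSUE_ROWS[name]
    return Layer(
        thickness=thickness if thickness is not None else row["thickness"],
        props_by_wavelength={
            wl: OpticalProperties(
                mu_s=row["mu_s"][i],
                mu_a=mu_a if mu_a is not None else row["mu_a"],
                g=row["g"],
                n=n,
            )
            for i, wl in enumerate(WAVELENGTHS)
        },
    )


def make_preset_model(
    name: str,
    wavelength: int = 770,
    *,
    matched_boundary: bool = False,
    tissue_n: float = DEFAULT_TISSUE_N,
) -> TissueModel:
    """Build one of the preset tissue models.

    Parameters
    ----------
    name : {"homogeneous_skin", "skin_subcutaneous", "gastric"}
    wavelength : {770, 830}
        Wavelength whose optical properties the transport engine will use
        (both wavelengths' properties are stored on every layer).
    matched_boundary : bool
        If True, set the ambient refractive index equal to the tissue index
        (no Fresnel reflection), for diffusion-limit comparisons.
    tissue_n : float
        Refractive index assigned to every tissue layer.

    Raises
    ------
    UnknownPresetError
        For an unknown preset name or wavelength.
    """
    wavelength = int(wavelength)
    if wavelength not in WAVELENGTHS:
        raise UnknownPresetError(
            f"unknown wavelength {wavelength} nm (choose from {WAVELENGTHS})"
        )
    if name == "homogeneous_skin":
        layers = (
            _tissue_layer(
                "skin", thickness=HOMOGENEOUS_DEPTH, mu_a=MEAN_TISSUE_MU_A, n=tissue_n
            ),
        )
    elif name == "skin_subcutaneous":
        layers = (
            _tissue_layer("skin", n=tissue_n),
            _tissue_layer("fat", n=tissue_n),
            _tissue_layer("muscle", n=tissue_n),
        )
    elif name == "gastric":
        layers = (_tissue_layer("gastric", n=tissue_n),)
    else:
        raise UnknownPresetError(
            f"unknown preset {name!r} (choose from {PRESET_NAMES})"
        )
    ambient = tissue_n if matched_boundary else DEFAULT_AMBIENT_N
    return TissueModel(
        layers=layers,
        wavelength=wavelength,
        label=name,
        ambient_n_top=ambient,
        ambient_n_bottom=ambient,
    )


def homogeneous_model(
    props: OpticalProperties,
    thickness: float = HOMOGENEOUS_DEPTH,
    wavelength: int = 770,
    label: str = "homogeneous",
    matched_boundary: bool = False,
) -> TissueModel:
    """Single-slab model with the same properties at both wavelengths."""
    layer = Layer(
        thickness=thickness,
        props_by_wavelength={wl: props for wl in WAVELENGTHS},
    )
    ambient = props.n if matched_boundary else DEFAULT_AMBIENT_N
    return TissueModel(
        layers=(layer,),
        wavelength=wavelength,
        label=label,
        ambient_n_top=ambient,
        ambient_n_bottom=ambient,
    )
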