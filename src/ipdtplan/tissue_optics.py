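"""Optical properties of segmented brain tissue at 635 nm.

The planning pipeline consumes a seven-class brain segmentation (CSF, grey
matter, white matter, necrotic tumor, non-enhancing tumor, enhancing tumor and
perilesional oedema).  Each class carries an absorption coefficient ``mu_a``
(per mm), a scattering coefficient ``mu_s`` (per mm), a Henyey–Greenstein
anisotropy factor ``g`` and a refractive index (1.40 for every cerebral tissue
subtype, so no internal Fresnel events occur during transport).

The default table ships as a versioned plain-text file
(``data/tissue_table_635nm.tsv``) and can be overridden with any file of the
same format, e.g. to explore alternative literature values.

This module also provides the standard analytic diffusion-theory quantities
(reduced scattering, effective attenuation, infinite-medium point-source
fluence rate) that serve as independent oracles for the Monte Carlo engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, Mapping, Optional, Tuple

import numpy as np

from .errors import UnknownTissueError
from .units import MM2_PER_CM2


class TissueLabel(IntEnum):
    """Integer coding of the segmentation classes used throughout the package."""

    BACKGROUND = 0
    CSF = 1
    GREY_MATTER = 2
    WHITE_MATTER = 3
    NECROTIC = 4
    NON_ENHANCING = 5
    ENHANCING = 6
    OEDEMA = 7


#: Labels that form the default treatment target (solid tumor compartments).
TUMOR_LABELS = (TissueLabel.NECROTIC, TissueLabel.NON_ENHANCING, TissueLabel.ENHANCING)


@dataclass(frozen=True)
class OpticalProperties:
    """Single-tissue optical properties at 635 nm.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, per mm (>= 0).
    mu_s : float
        Scattering coefficient, per mm (>= 0).
    g : float
        Scattering anisotropy (mean cosine of the scattering angle), in [-1, 1].
    n_ri : float
        Refractive index (>= 1).
    """

    mu_a: float
    mu_s: float
    g: float
    n_ri: float = 1.40

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be non-negative, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be non-negative, got {self.mu_s}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"anisotropy g must lie in [-1, 1], got {self.g}")
        if self.n_ri < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n_ri}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, per mm."""
        return self.mu_a + self.mu_s


def reduced_scattering(props: OpticalProperties) -> float:
    """Reduced scattering coefficient mu_s' = mu_s (1 - g), per mm."""
    return props.mu_s * (1.0 - props.g)


def diffusion_coefficient(props: OpticalProperties) -> float:
    """Diffusion coefficient D = 1 / (3 (mu_a + mu_s')), in mm."""
    return 1.0 / (3.0 * (props.mu_a + reduced_scattering(props)))


def effective_attenuation(props: OpticalProperties) -> float:
    """Effective attenuation mu_eff = sqrt(3 mu_a (mu_a + mu_s')), per mm."""
    return math.sqrt(3.0 * props.mu_a * (props.mu_a + reduced_scattering(props)))


def diffusion_point_fluence(props: OpticalProperties, power_mw: float, r_mm: float) -> float:
    """Diffusion-theory fluence rate of an isotropic point source, mW/cm^2.

    Infinite homogeneous medium solution
    ``phi(r) = P exp(-mu_eff r) / (4 pi D r)``, valid in scattering-dominated
    tissue (mu_s' >> mu_a) a few transport mean free paths from the source.
    Used as the independent far-field oracle for the Monte Carlo engine.

    Parameters
    ----------
    power_mw : float
        Source power in mW.
    r_mm : float
        Distance from the source in mm (> 0).
    """
    if r_mm <= 0:
        raise ValueError(f"distance r must be positive, got {r_mm}")
    mu_eff = effective_attenuation(props)
    d_mm = diffusion_coefficient(props)
    phi_per_mm2 = power_mw * math.exp(-mu_eff * r_mm) / (4.0 * math.pi * d_mm * r_mm)
    return phi_per_mm2 * MM2_PER_CM2


class TissueTable:
    """Mapping from integer tissue label to :class:`OpticalProperties`.

    The table always carries a background label whose packets are treated as
    escaped by the transport engine.
    """

    def __init__(
        self,
        entries: Mapping[int, OpticalProperties],
        names: Optional[Mapping[int, str]] = None,
        version: str = "custom",
    ):
        if not entries:
            raise ValueError("tissue table must contain at least one entry")
        self._entries: Dict[int, OpticalProperties] = {int(k): v for k, v in entries.items()}
        self._names: Dict[int, str] = {
            int(k): (names[k] if names and k in names else f"label_{int(k)}")
            for k in self._entries
        }
        self.version = version

    def lookup(self, label: int) -> OpticalProperties:
        """Return the properties registered for ``label``.

        Raises :class:`~ipdtplan.errors.UnknownTissueError` for an
        unregistered label.
        """
        try:
            return self._entries[int(label)]
        except KeyError:
            raise UnknownTissueError(int(label)) from None

    def name(self, label: int) -> str:
        self.lookup(label)
        return self._names[int(label)]

    def __contains__(self, label: int) -> bool:
        return int(label) in self._entries

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self._entries))

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def labels(self) -> Tuple[int, ...]:
        return tuple(sorted(self._entries))

    @property
    def max_label(self) -> int:
        return max(self._entries)

    def to_arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (mu_a, mu_s, g) arrays indexed by label, for the transport kernel.

        Unregistered labels in the range are zero-filled; the transport entry
        point rejects grids containing them before the kernel runs.
        """
        n = self.max_label + 1
        mu_a = np.zeros(n)
        mu_s = np.zeros(n)
        g = np.zeros(n)
        for lab, props in self._entries.items():
            mu_a[lab] = props.mu_a
            mu_s[lab] = props.mu_s
            g[lab] = props.g
        return mu_a, mu_s, g

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_tsv(cls, path) -> "TissueTable":
        """Read a table from the versioned plain-text format (see data/)."""
        entries: Dict[int, OpticalProperties] = {}
        names: Dict[int, str] = {}
        version = "unversioned"
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "version:" in line:
                    version = line.split("version:", 1)[1].strip()
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"malformed tissue table line: {raw!r}")
            label = int(fields[0])
            names[label] = fields[1]
            entries[label] = OpticalProperties(
                mu_a=float(fields[2]), mu_s=float(fields[3]),
                g=float(fields[4]), n_ri=float(fields[5]),
            )
        return cls(entries, names, version=version)

    def to_tsv(self, path) -> None:
        lines = [
            "# Optical properties table (per-mm coefficients).",
            f"# version: {self.version}",
            "# columns: label\tname\tmu_a\tmu_s\tg\tn_ri",
        ]
        for lab in self.labels:
            p = self._entries[lab]
            lines.append(
                f"{lab}\t{self._names[lab]}\t{p.mu_a!r}\t{p.mu_s!r}\t{p.g!r}\t{p.n_ri!r}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


_DEFAULT_TABLE: Optional[TissueTable] = None


def default_tissue_table() -> TissueTable:
    """The packaged 635 nm seven-tissue table (cached singleton)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(
            resources.files("ipdtplan.data") / "tissue_table_635nm.tsv"
        ) as p:
            _DEFAULT_TABLE = TissueTable.from_tsv(p)
    return _DEFAULT_TABLE


def lookup_properties(table: TissueTable, label: int) -> OpticalProperties:
    """Functional alias for :meth:`TissueTable.lookup`."""
    return table.lookup(label)
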