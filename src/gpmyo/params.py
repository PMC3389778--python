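"""Model parameters with provenance.

The reference parameter set ships as a YAML file (``data/reference_params.yaml``)
organized by module section.  Every entry carries a value, units, and a
provenance tag (``cited-source`` for values taken from the published source
models of this lineage, ``calibrated`` for values fixed by fitting the
whole-model outputs, ``chosen`` for free implementation choices).

For the numerical kernels the parameter set is flattened into a single
``float64`` array in a fixed order defined by :data:`SCHEMA`; the module
exposes one integer index constant per parameter (``P_<NAME>``) so that the
jitted right-hand-side code can address parameters by name at compile time.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

VALID_PROVENANCE = {"supplement", "cited-source", "calibrated", "chosen"}

# (section, name) in canonical flattening order.  Names are globally unique.
SCHEMA: tuple[tuple[str, str], ...] = (
    # --- cell geometry / exterior milieu / stimulus -----------------------
    ("cell", "cm"),
    ("cell", "v_myo"),
    ("cell", "v_sr"),
    ("cell", "v_mito"),
    ("cell", "v_ss"),
    ("cell", "na_o"),
    ("cell", "k_o"),
    ("cell", "ca_o"),
    ("cell", "stim_amp"),
    ("cell", "stim_dur"),
    # --- caru: coupled LCC-RyR release unit -------------------------------
    ("caru", "n_caru"),
    ("caru", "j_l"),
    ("caru", "j_r_single"),
    ("caru", "tau_ss"),
    ("caru", "lcc_alpha0"),
    ("caru", "lcc_v_alpha"),
    ("caru", "lcc_s_alpha"),
    ("caru", "lcc_beta0"),
    ("caru", "lcc_v_beta"),
    ("caru", "lcc_s_beta"),
    ("caru", "lcc_f"),
    ("caru", "lcc_g"),
    ("caru", "lcc_f_ca_ratio"),
    ("caru", "lcc_kcdi"),
    ("caru", "lcc_ka_cdi"),
    ("caru", "lcc_omega"),
    ("caru", "y_min"),
    ("caru", "y_vhalf"),
    ("caru", "y_slope"),
    ("caru", "tau_y0"),
    ("caru", "tau_y_amp"),
    ("caru", "tau_y_vmid"),
    ("caru", "tau_y_width"),
    ("caru", "ryr_n_act"),
    ("caru", "ryr_ka"),
    ("caru", "ryr_k21"),
    ("caru", "ryr_kb"),
    ("caru", "ryr_k32"),
    ("caru", "ryr_k34"),
    ("caru", "ryr_k41"),
    ("caru", "ryr_kinact_ca"),
    # --- sarcolemma -------------------------------------------------------
    ("sarcolemma", "gna"),
    ("sarcolemma", "gk1"),
    ("sarcolemma", "gkr"),
    ("sarcolemma", "gks_scale"),
    ("sarcolemma", "iks_deact_scale"),
    ("sarcolemma", "iks_variant"),
    ("sarcolemma", "gkp"),
    ("sarcolemma", "gkatp"),
    ("sarcolemma", "inak_max"),
    ("sarcolemma", "km_nai_nak"),
    ("sarcolemma", "km_ko_nak"),
    ("sarcolemma", "ncx_vmax"),
    ("sarcolemma", "ncx_km_ca_act"),
    ("sarcolemma", "ncx_eta"),
    ("sarcolemma", "ncx_ksat"),
    ("sarcolemma", "ncx_km_nai"),
    ("sarcolemma", "ncx_km_nao"),
    ("sarcolemma", "ncx_km_cai"),
    ("sarcolemma", "ncx_km_cao"),
    ("sarcolemma", "ipca_max"),
    ("sarcolemma", "km_pca"),
    ("sarcolemma", "gcab"),
    ("sarcolemma", "gnab"),
    ("sarcolemma", "ito_enabled"),
    ("sarcolemma", "gto"),
    # --- ca_cycling -------------------------------------------------------
    ("ca_cycling", "serca_vmaxf"),
    ("ca_cycling", "serca_vmaxr"),
    ("ca_cycling", "serca_kfb"),
    ("ca_cycling", "serca_krb"),
    ("ca_cycling", "serca_nfb"),
    ("ca_cycling", "serca_nrb"),
    ("ca_cycling", "serca_km_atp"),
    ("ca_cycling", "cmdn_tot"),
    ("ca_cycling", "cmdn_kon"),
    ("ca_cycling", "cmdn_koff"),
    ("ca_cycling", "csqn_tot"),
    ("ca_cycling", "csqn_kon"),
    ("ca_cycling", "csqn_koff"),
    # --- mitochondria -----------------------------------------------------
    ("mitochondria", "cmito"),
    ("mitochondria", "nad_tot"),
    ("mitochondria", "adn_tot_m"),
    ("mitochondria", "vmax_o"),
    ("mitochondria", "km_o_nadh"),
    ("mitochondria", "dpsi_o_half"),
    ("mitochondria", "kappa_o"),
    ("mitochondria", "nh_o"),
    ("mitochondria", "nh_sdh"),
    ("mitochondria", "nh_f1"),
    ("mitochondria", "vmax_f1"),
    ("mitochondria", "km_f1_adp"),
    ("mitochondria", "dpsi_f1_half"),
    ("mitochondria", "kappa_f1"),
    ("mitochondria", "vmax_ant"),
    ("mitochondria", "f_ant"),
    ("mitochondria", "g_h_leak"),
    ("mitochondria", "vmax_uni"),
    ("mitochondria", "uni_ktrans"),
    ("mitochondria", "uni_kact"),
    ("mitochondria", "uni_l"),
    ("mitochondria", "uni_na_exp"),
    ("mitochondria", "uni_dpsi0"),
    ("mitochondria", "vmuni_scale"),
    ("mitochondria", "vmax_mncx"),
    ("mitochondria", "mncx_km_na"),
    ("mitochondria", "mncx_km_ca"),
    ("mitochondria", "mncx_n_na"),
    ("mitochondria", "vmax_nhe"),
    ("mitochondria", "nhe_km_na"),
    ("mitochondria", "nhe_km_h"),
    ("mitochondria", "h_i"),
    ("mitochondria", "h_m"),
    ("mitochondria", "f_ca_m"),
    ("mitochondria", "accoa"),
    ("mitochondria", "vmax_cs"),
    ("mitochondria", "km_oaa_cs"),
    ("mitochondria", "vmax_idh"),
    ("mitochondria", "km_isoc"),
    ("mitochondria", "ka_ca_idh"),
    ("mitochondria", "km_nad_idh"),
    ("mitochondria", "vmax_kgdh"),
    ("mitochondria", "km_akg"),
    ("mitochondria", "ka_ca_kgdh"),
    ("mitochondria", "vmax_sl"),
    ("mitochondria", "km_scoa"),
    ("mitochondria", "km_adp_sl"),
    ("mitochondria", "vmax_sdh"),
    ("mitochondria", "km_suc"),
    ("mitochondria", "vmax_fh"),
    ("mitochondria", "keq_fh"),
    ("mitochondria", "vmax_mdh"),
    ("mitochondria", "km_mal"),
    ("mitochondria", "km_nad_mdh"),
    # --- contraction ------------------------------------------------------
    ("contraction", "ltrpn_tot"),
    ("contraction", "ltrpn_kon"),
    ("contraction", "ltrpn_koff"),
    ("contraction", "htrpn_tot"),
    ("contraction", "htrpn_kon"),
    ("contraction", "htrpn_koff"),
    ("contraction", "xb_f01"),
    ("contraction", "xb_f12"),
    ("contraction", "xb_f23"),
    ("contraction", "xb_g01"),
    ("contraction", "xb_g12"),
    ("contraction", "xb_g23"),
    ("contraction", "k_pn_basic"),
    ("contraction", "perm50"),
    ("contraction", "n_perm"),
    ("contraction", "fnorm_max"),
    ("contraction", "fmax_mn"),
    ("contraction", "xsec_area"),
    ("contraction", "c_atpase"),
    ("contraction", "basal_atpase"),
    # --- cytosolic energetics --------------------------------------------
    ("energetics", "atot_i"),
    ("energetics", "cr_tot"),
    ("energetics", "kck"),
    ("energetics", "keq_ck"),
)

N_PARAMS = len(SCHEMA)
PARAM_NAMES: tuple[str, ...] = tuple(name for _, name in SCHEMA)
PARAM_INDEX: dict[str, int] = {name: i for i, name in enumerate(PARAM_NAMES)}

# Compile-time index constants for the jitted kernels (P_<NAME>).
for _i, _name in enumerate(PARAM_NAMES):
    globals()["P_" + _name.upper()] = _i
del _i, _name

IKS_VISWANATHAN99 = 0.0
IKS_ZENG95 = 1.0


@dataclass
class ParamEntry:
    value: float
    units: str
    provenance: str


class Parameters(Mapping[str, ParamEntry]):
    """Validated, provenance-tagged model parameter set."""

    def __init__(self, entries: dict[str, ParamEntry]):
        missing = [n for n in PARAM_NAMES if n not in entries]
        extra = [n for n in entries if n not in PARAM_INDEX]
        if missing or extra:
            raise ValueError(
                f"parameter schema mismatch: missing={missing!r} extra={extra!r}"
            )
        bad = {n: e.provenance for n, e in entries.items()
               if e.provenance not in VALID_PROVENANCE}
        if bad:
            raise ValueError(f"invalid provenance tags: {bad!r}")
        self._entries = dict(entries)

    # -- mapping protocol --------------------------------------------------
    def __getitem__(self, name: str) -> ParamEntry:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return N_PARAMS

    def value(self, name: str) -> float:
        return self._entries[name].value

    def as_array(self) -> np.ndarray:
        """Flatten to the canonical float64 vector used by the kernels."""
        return np.array([self._entries[n].value for n in PARAM_NAMES])

    def with_values(self, **overrides: float) -> "Parameters":
        """Return a copy with selected values replaced (provenance kept)."""
        entries = _copy.deepcopy(self._entries)
        for name, val in overrides.items():
            if name not in entries:
                raise KeyError(f"unknown parameter {name!r}")
            entries[name].value = float(val)
        return Parameters(entries)

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "Parameters":
        entries: dict[str, ParamEntry] = {}
        for section, name in SCHEMA:
            sec = data.get(section, {})
            if name not in sec:
                raise ValueError(f"missing parameter {section}.{name}")
            raw = sec[name]
            entries[name] = ParamEntry(
                value=float(raw["value"]),
                units=str(raw.get("units", "")),
                provenance=str(raw.get("provenance", "chosen")),
            )
        # reject unknown keys (schema-validated: no unreferenced parameters)
        known = {s: set() for s, _ in SCHEMA}
        for s, n in SCHEMA:
            known[s].add(n)
        for section, sec in data.items():
            if section not in known:
                raise ValueError(f"unknown parameter section {section!r}")
            for name in sec:
                if name not in known[section]:
                    raise ValueError(f"unknown parameter {section}.{name}")
        return cls(entries)

    @classmethod
    def from_yaml(cls, path=None) -> "Parameters":
        if path is None:
            ref = resources.files("gpmyo.data").joinpath("reference_params.yaml")
            with ref.open("r") as fh:
                data = yaml.safe_load(fh)
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out: dict[str, dict] = {}
        for section, name in SCHEMA:
            e = self._entries[name]
            out.setdefault(section, {})[name] = {
                "value": e.value, "units": e.units, "provenance": e.provenance,
            }
        return out


def load_reference() -> Parameters:
    """The versioned reference parameter set shipped with the package."""
    return Parameters.from_yaml()
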