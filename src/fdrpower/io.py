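"""Plain-text design files describing per-feature effect vectors.

A design file is delimited text (TSV or CSV, header row required) with one
row per distinct feature configuration and the family-specific parameter
columns below.  An optional integer ``count`` column repeats a row, so
"9,900 null genes and 100 at log_fc = 1" is two lines rather than 10,000.
An optional ``family`` column (one unique value) can name the family in
the file instead of passing it to :func:`read_design`.

======================  =================================
family                  required columns
======================  =================================
sign                    theta           (optional theta0)
one_sample_t            delta
two_sample_t            delta
ranksum / signedrank    p_prime
fisher / twoprop        p1, p2
corr                    rho
poisson                 lambda1, lambda2
negbin                  log_fc, mu, cv
anova                   mean_1 ... mean_k, sigma
cox                     log_hr          (optional v, default 1)
======================  =================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import EffectProfile

__all__ = ["read_design", "profile_from_frame"]

_SCHEMAS = {
    "sign": (("theta",), ("theta0",)),
    "one_sample_t": (("delta",), ()),
    "two_sample_t": (("delta",), ()),
    "ranksum": (("p_prime",), ()),
    "signedrank": (("p_prime",), ()),
    "fisher": (("p1", "p2"), ()),
    "twoprop": (("p1", "p2"), ()),
    "corr": (("rho",), ()),
    "poisson": (("lambda1", "lambda2"), ()),
    "negbin": (("log_fc", "mu", "cv"), ()),
    "cox": (("log_hr",), ("v",)),
    # anova handled separately (variable number of mean_* columns)
}


class DesignFileError(ValueError):
    """Raised for malformed design files, with the offending location."""


def read_design(path, family: str | None = None, require_false_nulls: bool = True) -> EffectProfile:
    """Read a delimited design file into an expanded :class:`EffectProfile`.

    Parameters
    ----------
    path : str or path-like
        TSV or CSV file (delimiter sniffed) with a header row.
    family : str, optional
        Test family; may instead be given as a single-valued ``family``
        column in the file.
    require_false_nulls : bool
        When True (default), reject designs whose every feature satisfies
        the null — such a design has no average power to target.
    """
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        frame = pd.read_csv(path, sep=sep, comment="#")
    except OSError as exc:
        raise DesignFileError(f"{path}: cannot read design file: {exc}") from exc
    except Exception as exc:
        raise DesignFileError(f"{path}: cannot parse design file: {exc}") from exc
    return profile_from_frame(frame, family=family, require_false_nulls=require_false_nulls, where=str(path))


def profile_from_frame(frame: pd.DataFrame, family: str | None = None,
                       require_false_nulls: bool = True, where: str = "design") -> EffectProfile:
    """Build an :class:`EffectProfile` from an in-memory design table."""
    frame = frame.copy()
    frame.columns = [str(c).strip().lower() for c in frame.columns]

    if "family" in frame.columns:
        tags = frame.pop("family").astype(str).str.strip().str.lower().unique()
        if len(tags) != 1:
            raise DesignFileError(f"{where}: 'family' column must have one unique value; got {list(tags)}")
        if family is not None and family.lower() != tags[0]:
            raise DesignFileError(f"{where}: family argument {family!r} conflicts with file family {tags[0]!r}")
        family = tags[0]
    if family is None:
        raise DesignFileError(f"{where}: no family given and no 'family' column present")
    family = family.lower()

    counts = np.ones(len(frame), dtype=int)
    if "count" in frame.columns:
        raw = frame.pop("count")
        try:
            counts = raw.astype(int).to_numpy()
        except (TypeError, ValueError) as exc:
            raise DesignFileError(f"{where}: non-integer 'count' value: {exc}") from exc
        bad = np.nonzero(counts < 1)[0]
        if bad.size:
            raise DesignFileError(f"{where}: line {bad[0] + 2}: 'count' must be a positive integer")

    if family == "anova":
        profile = _anova_profile(frame, counts, where)
    else:
        if family not in _SCHEMAS:
            raise DesignFileError(f"{where}: unknown family {family!r}")
        required, optional = _SCHEMAS[family]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise DesignFileError(
                f"{where}: family {family!r} requires columns {list(required)}; missing {missing}"
            )
        extra = [c for c in frame.columns if c not in required + optional]
        if extra:
            raise DesignFileError(f"{where}: unexpected columns for family {family!r}: {extra}")
        cols = {}
        for c in list(required) + [c for c in optional if c in frame.columns]:
            values = pd.to_numeric(frame[c], errors="coerce")
            bad = np.nonzero(values.isna().to_numpy())[0]
            if bad.size:
                raise DesignFileError(
                    f"{where}: line {bad[0] + 2}: non-numeric value in column {c!r}"
                )
            cols[c] = np.repeat(values.to_numpy(dtype=float), counts)
        profile = _build(family, cols)

    if len(profile.null_mask) < 2:
        raise DesignFileError(f"{where}: expanded design must contain at least 2 features")
    if require_false_nulls and profile.null_mask.all():
        raise DesignFileError(
            f"{where}: every feature satisfies the null hypothesis; "
            "a design search needs at least one false-null feature"
        )
    return profile


def _build(family, cols):
    if family == "sign":
        return EffectProfile.sign(cols["theta"], cols.get("theta0", 0.5))
    if family == "one_sample_t":
        return EffectProfile.one_sample_t(cols["delta"])
    if family == "two_sample_t":
        return EffectProfile.two_sample_t(cols["delta"])
    if family == "ranksum":
        return EffectProfile.ranksum(cols["p_prime"])
    if family == "signedrank":
        return EffectProfile.signedrank(cols["p_prime"])
    if family == "fisher":
        return EffectProfile.fisher(cols["p1"], cols["p2"])
    if family == "twoprop":
        return EffectProfile.twoprop(cols["p1"], cols["p2"])
    if family == "corr":
        return EffectProfile.corr(cols["rho"])
    if family == "poisson":
        return EffectProfile.poisson(cols["lambda1"], cols["lambda2"])
    if family == "negbin":
        return EffectProfile.negbin(cols["log_fc"], cols["mu"], cols["cv"])
    if family == "cox":
        return EffectProfile.cox(cols["log_hr"], cols.get("v", 1.0))
    raise AssertionError(family)


def _anova_profile(frame, counts, where):
    mean_cols = sorted(
        (c for c in frame.columns if c.startswith("mean_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    if len(mean_cols) < 2:
        raise DesignFileError(f"{where}: anova needs columns mean_1, mean_2, ... (>= 2 groups)")
    if "sigma" not in frame.columns:
        raise DesignFileError(f"{where}: anova requires a 'sigma' column")
    extra = [c for c in frame.columns if c not in mean_cols + ["sigma"]]
    if extra:
        raise DesignFileError(f"{where}: unexpected columns for family 'anova': {extra}")
    for c in mean_cols + ["sigma"]:
        values = pd.to_numeric(frame[c], errors="coerce")
        bad = np.nonzero(values.isna().to_numpy())[0]
        if bad.size:
            raise DesignFileError(f"{where}: line {bad[0] + 2}: non-numeric value in column {c!r}")
    means = np.repeat(frame[mean_cols].to_numpy(dtype=float), counts, axis=0)
    sigma = np.repeat(frame["sigma"].to_numpy(dtype=float), counts)
    return EffectProfile.anova(means, sigma)
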