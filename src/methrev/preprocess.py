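"""Signal-to-beta conversion, detection masking, and probe filtering.

The beta value of a CpG is M / (M + U + offset) where M and U are the
methylated and unmethylated array intensities and the offset (default 100)
regularizes low-intensity probes; with a positive offset the value is
strictly below 1.  Cells whose detection p-value is >= alpha (default
0.01) are indistinguishable from background and are masked to missing.
Probes on the sex chromosomes, and probes whose interrogating
oligonucleotide carries a known SNP within its last 10 bases, are removed
before any differential test.

Between-array normalization is not performed here: input signal pairs or
beta matrices are assumed already normalized (e.g. by minfi's control-probe
normalization when starting from IDATs).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ProbeManifest, SignalPairMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)


def compute_beta(signals: SignalPairMatrix, offset: float = 100.0) -> BetaMatrix:
    """Convert intensity pairs to beta values: M / (M + U + offset).

    With ``offset=0`` the pure ratio is recovered; cells where
    M + U + offset == 0 are undefined and become missing.
    """
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    m = signals.methylated.to_numpy(dtype=float)
    u = signals.unmethylated.to_numpy(dtype=float)
    denom = m + u + offset
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(denom > 0, m / denom, np.nan)
    return BetaMatrix(pd.DataFrame(beta, index=signals.probe_ids,
                                   columns=signals.sample_ids))


def apply_detection_mask(beta: BetaMatrix, detection_p: pd.DataFrame,
                         alpha: float = 0.01) -> BetaMatrix:
    """Mask beta values whose detection p-value is >= alpha.

    The boundary is inclusive on removal: a cell with p exactly equal to
    alpha is masked.  Cells with missing detection p are left unchanged.
    """
    if not (0 < alpha <= 1):
        raise ValidationError("alpha must be in (0, 1]")
    if not detection_p.index.equals(beta.probe_ids) or \
            not detection_p.columns.equals(beta.sample_ids):
        raise ValidationError("detection p matrix ids do not match beta matrix")
    p = detection_p.to_numpy(dtype=float)
    masked = beta.values.mask(pd.DataFrame(p >= alpha, index=beta.probe_ids,
                                           columns=beta.sample_ids))
    n_masked = int((p >= alpha).sum())
    logger.info("detection mask (alpha=%g): %d of %d cells removed",
                alpha, n_masked, p.size)
    return BetaMatrix(masked)


def filter_probes(beta: BetaMatrix, manifest: ProbeManifest,
                  on_missing: str = "error") -> BetaMatrix:
    """Drop sex-chromosome probes and probes with a SNP in the last 10 bases.

    Row order of surviving probes is preserved.  Probes absent from the
    manifest raise by default; ``on_missing='drop'`` downgrades to a logged
    warning and removes them (silent probe loss would corrupt downstream
    counts, so the default is strict).
    """
    if on_missing not in ("error", "drop"):
        raise ValidationError("on_missing must be 'error' or 'drop'")
    present = beta.probe_ids.isin(manifest.table.index)
    if not present.all():
        absent = list(beta.probe_ids[~present])
        if on_missing == "error":
            raise ValidationError(
                f"{len(absent)} probes absent from manifest, e.g. {absent[:5]}")
        logger.warning("dropping %d probes absent from manifest", len(absent))
    kept_ids = beta.probe_ids[present]
    info = manifest.table.loc[kept_ids]
    bad = manifest.is_sex_chromosome().loc[kept_ids] | info["snp_in_last_10_bases"]
    survivors = kept_ids[~bad.to_numpy()]
    logger.info("probe filter: %d sex-chromosome/SNP probes removed, %d kept",
                int(bad.sum()), len(survivors))
    return beta.subset_probes(survivors)
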