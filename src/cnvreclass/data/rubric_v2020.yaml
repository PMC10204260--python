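# Point table for the 2020 ACMG/ClinGen semiquantitative CNV classification
# framework, transcribed (as a machine-derivable subset) into a versioned,
# auditable config.  Points are in units of the published score; thresholds
# are stored in hundredths (fixed point) to avoid float-boundary
# misclassification at the 0.99 / 0.90 edges.
#
# Each section entry gives the allowed point range [min, max] and the
# default assigned by the automatic evidence builder; curators may choose
# any in-range value (merge_manual).  Loss rubric codes start with L, gain
# codes with G; a bundle must draw from exactly one rubric.

version: v2020
thresholds_hundredths:
  pathogenic_min: 99        # score >= 0.99            -> pathogenic
  likely_pathogenic_min: 90 # 0.90 <= score <= 0.98    -> likely pathogenic
  likely_benign_max: -90    # -0.98 <= score <= -0.90  -> likely benign
  benign_max: -99           # score <= -0.99           -> benign
  # everything in between (-0.89 .. 0.89)              -> uncertain

sections:
  loss:
    L1A: {min: 0.0, max: 0.0, default: 0.0,
          description: "Contains protein-coding or other known functionally important elements"}
    L1B: {min: -0.6, max: 0.0, default: -0.6,
          description: "Does NOT contain protein-coding or known functionally important elements"}
    L2A: {min: 0.0, max: 1.0, default: 1.0,
          description: "Complete overlap of an established HI gene or region"}
    L2B: {min: 0.0, max: 0.0, default: 0.0,
          description: "Partial overlap of an established HI region"}
    L2C: {min: 0.0, max: 0.9, default: 0.9,
          description: "Partial overlap of an established HI gene involving coding sequence"}
    L2F: {min: -1.0, max: 0.0, default: -1.0,
          description: "Completely contained within an established benign CNV region"}
    L2G: {min: 0.0, max: 0.0, default: 0.0,
          description: "Overlaps an established benign region with additional material"}
    L3A: {min: 0.0, max: 0.0, default: 0.0,
          description: "0-24 protein-coding genes"}
    L3B: {min: 0.45, max: 0.45, default: 0.45,
          description: "25-34 protein-coding genes"}
    L3C: {min: 0.9, max: 0.9, default: 0.9,
          description: "35 or more protein-coding genes"}
    L4:  {min: -0.9, max: 0.9, default: 0.0,
          description: "Published case evidence for the locus (aggregated, capped)"}
    L4O: {min: -1.0, max: 0.0, default: -1.0,
          description: "Overlap with common population variation"}
    L5A: {min: 0.0, max: 0.45, default: 0.45,
          description: "De novo occurrence in the proband"}
    L5D: {min: -0.45, max: 0.0, default: -0.3,
          description: "Inherited from an apparently unaffected parent"}
    L5F: {min: 0.0, max: 0.0, default: 0.0,
          description: "Inheritance information uninformative (unknown / parent status unassessed)"}
  gain:
    G1A: {min: 0.0, max: 0.0, default: 0.0,
          description: "Contains protein-coding or other known functionally important elements"}
    G1B: {min: -0.6, max: 0.0, default: -0.6,
          description: "Does NOT contain protein-coding or known functionally important elements"}
    G2A: {min: 0.0, max: 1.0, default: 1.0,
          description: "Complete overlap of an established TS gene or region"}
    G2B: {min: 0.0, max: 0.0, default: 0.0,
          description: "Partial overlap of an established TS region"}
    G2C: {min: -1.0, max: 0.0, default: -1.0,
          description: "Identical in gene content to an established benign gain region"}
    G2D: {min: -1.0, max: 0.0, default: -1.0,
          description: "Smaller than an established benign gain, breakpoints within"}
    G3A: {min: 0.0, max: 0.0, default: 0.0,
          description: "0-34 protein-coding genes"}
    G3B: {min: 0.45, max: 0.45, default: 0.45,
          description: "35-49 protein-coding genes"}
    G3C: {min: 0.9, max: 0.9, default: 0.9,
          description: "50 or more protein-coding genes"}
    G4:  {min: -0.9, max: 0.9, default: 0.0,
          description: "Published case evidence for the locus (aggregated, capped)"}
    G4O: {min: -1.0, max: 0.0, default: -1.0,
          description: "Overlap with common population variation"}
    G5A: {min: 0.0, max: 0.45, default: 0.45,
          description: "De novo occurrence in the proband"}
    G5D: {min: -0.45, max: 0.0, default: -0.3,
          description: "Inherited from an apparently unaffected parent"}
    G5F: {min: 0.0, max: 0.0, default: 0.0,
          description: "Inheritance information uninformative (unknown / parent status unassessed)"}
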