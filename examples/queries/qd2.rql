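# Knockout semantics: rules from a binary "this TF is deleted in this
# sample" annotation (table "ann", one 0/1 column per TF) to strong
# expression responses in the raw expression table "expr".  Attribute
# lists are dataset-qualified because a TF can appear in both tables
# (deletion flag vs its own expression).  Edit the OVER lists to match
# your column names; the response threshold (2.0) is in raw baseline
# units.
FINDRULES
  SCOPE t1 IN (expr)
  HAVING ko: t1.$a = 1 OVER ann.TF01, ann.TF02, ann.TF03, ann.TF04, ann.TF05
  AND down: t1.$a <= -2.0 OVER expr.G01, expr.G02, expr.G03, expr.G04, expr.G05
  AND up: t1.$a >= 2.0 OVER expr.G01, expr.G02, expr.G03, expr.G04, expr.G05;
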