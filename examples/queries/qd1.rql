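# Co-expression semantics: rules between strongly over- and
# under-expressed genes.  Expects a scaled/centered expression table
# bound as "expr"; the threshold (here 1.0) is in standard-deviation
# units.  Edit the OVER lists to restrict the attributes mined.
FINDRULES
  SCOPE t1 IN (expr)
  HAVING high: t1.$a >= 1.0 OVER *
  AND low: t1.$a <= -1.0 OVER *;
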