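# Duplicate-rule detection: join rules on a shared bqbiol:is identity.
# The FILTER prevents comparing a rule with itself; STR ordering
# deduplicates the symmetric pair.  Native implementation:
# rbmannot.analyses.find_duplicate_rules.
PREFIX rdf:    <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rbmo:   <http://purl.org/rbm/rbmo#>
PREFIX bqbiol: <http://biomodels.net/biology-qualifiers/>

SELECT DISTINCT ?ruleA ?ruleB ?identity
WHERE {
  ?ruleA rdf:type rbmo:Rule ; bqbiol:is ?identity .
  ?ruleB rdf:type rbmo:Rule ; bqbiol:is ?identity .
  FILTER (STR(?ruleA) < STR(?ruleB))
}
ORDER BY ?ruleA ?ruleB ?identity
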