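# Contact-map derivation: pairs of (agent, site) bound by a shared bond
# URI in some rule pattern.  Native implementation:
# rbmannot.analyses.contact_map.
PREFIX rdf:  <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rbmo: <http://purl.org/rbm/rbmo#>

SELECT DISTINCT ?agentA ?siteA ?agentB ?siteB ?bond
WHERE {
  ?statusA rbmo:isBoundBy ?bond ;
           rbmo:isStatusOf ?siteA ;
           rbmo:agent ?agentA .
  ?statusB rbmo:isBoundBy ?bond ;
           rbmo:isStatusOf ?siteB ;
           rbmo:agent ?agentB .
  FILTER (STR(?statusA) < STR(?statusB))
}
ORDER BY ?agentA ?siteA ?agentB ?siteB
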