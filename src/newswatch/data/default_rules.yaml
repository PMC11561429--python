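# Illustrative rule sets for the six health-workforce surveillance topics.
# NOT an authoritative expert rule base: deployments replace this file with
# rules designed by domain experts for their corpus. Structure demonstrates
# the DSL: inclusion rules at sentence/title scope, exclusion rules as NOT.
- topic_id: 1
  topic_name: workforce_policy
  rules:
    - op: or
      children:
        - op: match
          scope: sentence
          list_name: workforce_terms
          keywords: [workforce, staffing, recruitment, retention, bonuses, payroll]
        - op: match
          scope: title
          list_name: workforce_terms
          keywords: [workforce, staffing, recruitment, retention, bonuses, payroll]
    - op: not
      child:
        op: match
        scope: body
        list_name: offtopic_terms
        keywords: [football, celebrity, touchdown]
- topic_id: 2
  topic_name: education
  rules:
    - op: or
      children:
        - op: match
          scope: sentence
          list_name: education_terms
          keywords: [curriculum, residency, trainees, coursework, accreditation, scholarships]
        - op: match
          scope: title
          list_name: education_terms
          keywords: [curriculum, residency, trainees, coursework, accreditation, scholarships]
    - op: not
      child:
        op: match
        scope: body
        list_name: offtopic_terms
        keywords: [football, celebrity, touchdown]
- topic_id: 3
  topic_name: vaccination
  rules:
    - op: or
      children:
        - op: match
          scope: sentence
          list_name: vaccination_terms
          keywords: [vaccination, vaccine, booster, immunization, doses, inoculation]
        - op: match
          scope: title
          list_name: vaccination_terms
          keywords: [vaccination, vaccine, booster, immunization, doses, inoculation]
    - op: not
      child:
        op: match
        scope: body
        list_name: offtopic_terms
        keywords: [football, celebrity, touchdown]
- topic_id: 4
  topic_name: strikes
  rules:
    - op: or
      children:
        - op: match
          scope: sentence
          list_name: strike_terms
          keywords: [strike, walkout, picket, stoppage, unions, negotiations]
        - op: match
          scope: title
          list_name: strike_terms
          keywords: [strike, walkout, picket, stoppage, unions, negotiations]
    - op: not
      child:
        op: match
        scope: body
        list_name: offtopic_terms
        keywords: [football, celebrity, touchdown]
- topic_id: 5
  topic_name: mental_health
  rules:
    - op: or
      children:
        - op: match
          scope: sentence
          list_name: mental_health_terms
          keywords: [burnout, stress, anxiety, depression, counselling, wellbeing]
        - op: match
          scope: title
          list_name: mental_health_terms
          keywords: [burnout, stress, anxiety, depression, counselling, wellbeing]
    - op: not
      child:
        op: match
        scope: body
        list_name: offtopic_terms
        keywords: [football, celebrity, touchdown]
- topic_id: 6
  topic_name: infections_deaths
  rules:
    - op: or
      children:
        - op: match
          scope: sentence
          list_name: infection_terms
          keywords: [infections, fatalities, infected, deaths, mortality, quarantined]
        - op: match
          scope: title
          list_name: infection_terms
          keywords: [infections, fatalities, infected, deaths, mortality, quarantined]
    - op: not
      child:
        op: match
        scope: body
        list_name: offtopic_terms
        keywords: [football, celebrity, touchdown]
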