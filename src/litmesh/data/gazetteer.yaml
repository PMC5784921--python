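# Country gazetteer: canonical name -> surface forms found in MEDLINE
# affiliation (AD) fields.  The canonical name itself always matches.
United States:
  - USA
  - U.S.A
  - US
  - U.S
  - United States of America
  - United States of North America
United Kingdom:
  - UK
  - U.K
  - England
  - Scotland
  - Wales
  - Northern Ireland
  - Great Britain
Canada: []
Australia: []
Switzerland: []
Norway: []
New Zealand: []
China:
  - People's Republic of China
  - PR China
  - P.R. China
Israel: []
Sweden: []
Spain: []
Netherlands:
  - The Netherlands
Germany:
  - Federal Republic of Germany
Brazil:
  - Brasil
Belgium: []
France: []
Denmark: []
Finland: []
Hungary: []
India: []
Italy:
  - Italia
Japan: []
Taiwan: []
Ireland: []
Poland: []
Greece: []
Croatia: []
Cameroon: []
Mexico:
  - México
Austria: []
Portugal: []
Russia:
  - Russian Federation
South Africa: []
South Korea:
  - Korea
  - Republic of Korea
Turkey: []
Argentina: []
Chile: []
Colombia: []
Cuba: []
Czech Republic:
  - Czechia
Egypt: []
Iran: []
Nigeria: []
Pakistan: []
Peru: []
Philippines: []
Saudi Arabia: []
Singapore: []
Thailand: []
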